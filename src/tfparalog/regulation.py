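"""Classification of genes into knockdown regulation groups.

Given per-gene modulation calls under three RNAi conditions — knockdown of
factor 1 alone (si1), of factor 2 alone (si2), and of both together (si12) —
genes fall into four groups:

- A: preferentially regulated by factor 1 (si1 alone modulates, si2 does not)
- B: preferentially regulated by factor 2 (symmetric)
- C: redundantly regulated (only the double knockdown modulates)
- D: complementarily regulated (both single knockdowns modulate in the same
  direction and the double knockdown has a strictly stronger effect)

Genes with no modulated condition are 'none'. Two flags mark edge cases the
rules alone do not resolve: 'discordant' when the two single knockdowns move
the gene in opposite directions, and 'both_nonadditive' when both singles
modulate but the double effect is not stronger than the strongest single.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ConditionCall",
    "GeneRegulationCalls",
    "GroupAssignment",
    "classify_gene",
    "classify_genes",
    "apply_fc_filter",
    "group_summary",
    "read_calls_table",
    "write_assignments",
]

CONDITIONS = ("si1", "si2", "si12")


@dataclass(frozen=True)
class ConditionCall:
    """One condition's call: was the transcript significantly modulated
    (versus both control conditions), in which direction, at what signed
    fold change (|fc| >= 1, sign gives direction)."""

    modulated: bool
    direction: str | None = None  # up | down
    fc: float | None = None

    def __post_init__(self) -> None:
        if self.modulated:
            if self.direction not in ("up", "down"):
                raise ValueError("modulated call needs direction up/down")
            if self.fc is None:
                raise ValueError("modulated call needs a fold change")
            if (self.fc > 0) != (self.direction == "up"):
                raise ValueError(
                    f"fc sign {self.fc} contradicts direction {self.direction}"
                )
        else:
            if self.direction is not None or self.fc is not None:
                raise ValueError("unmodulated call must omit direction and fc")


@dataclass(frozen=True)
class GeneRegulationCalls:
    gene: str
    si1: ConditionCall
    si2: ConditionCall
    si12: ConditionCall


@dataclass(frozen=True)
class GroupAssignment:
    gene: str
    group: str  # A | B | C | D | none
    direction: str | None
    discordant: bool = False
    both_nonadditive: bool = False
    max_abs_fc: float = 0.0


def classify_gene(calls: GeneRegulationCalls) -> GroupAssignment:
    """Map one gene's three-condition calls onto group A/B/C/D/none.

    A and B ignore the double-knockdown call (a single knockdown of the
    other factor may merely strengthen the effect). D demands same-direction
    single effects and |fc(si12)| strictly above the strongest single; when
    both singles modulate but that strength condition fails, the gene keeps
    group D's precondition flags but is assigned 'none' with
    both_nonadditive set, and opposite-direction singles set 'discordant'.
    """
    s1, s2, s12 = calls.si1, calls.si2, calls.si12
    fcs = [abs(c.fc) for c in (s1, s2, s12) if c.modulated]
    max_fc = max(fcs) if fcs else 0.0

    if s1.modulated and not s2.modulated:
        return GroupAssignment(calls.gene, "A", s1.direction, max_abs_fc=max_fc)
    if s2.modulated and not s1.modulated:
        return GroupAssignment(calls.gene, "B", s2.direction, max_abs_fc=max_fc)
    if s1.modulated and s2.modulated:
        if s1.direction != s2.direction:
            return GroupAssignment(
                calls.gene, "none", None, discordant=True, max_abs_fc=max_fc
            )
        stronger = s12.modulated and abs(s12.fc) > max(abs(s1.fc), abs(s2.fc))
        if stronger:
            return GroupAssignment(calls.gene, "D", s1.direction, max_abs_fc=max_fc)
        return GroupAssignment(
            calls.gene, "none", s1.direction, both_nonadditive=True,
            max_abs_fc=max_fc,
        )
    if s12.modulated:
        return GroupAssignment(calls.gene, "C", s12.direction, max_abs_fc=max_fc)
    return GroupAssignment(calls.gene, "none", None)


def classify_genes(calls: list[GeneRegulationCalls]) -> list[GroupAssignment]:
    return [classify_gene(c) for c in calls]


def apply_fc_filter(
    assignments: list[GroupAssignment], min_abs_fc: float = 1.5
) -> list[GroupAssignment]:
    """Keep genes whose strongest modulated |fold change| meets the
    (inclusive) threshold."""
    if min_abs_fc <= 1:
        raise ValueError(f"min_abs_fc must be > 1, got {min_abs_fc}")
    return [a for a in assignments if a.max_abs_fc >= min_abs_fc]


def group_summary(assignments: list[GroupAssignment]) -> pd.DataFrame:
    """Counts per group x direction for the four groups (A-D)."""
    table = pd.DataFrame(
        0, index=list("ABCD"), columns=["up", "down"], dtype=int
    )
    for a in assignments:
        if a.group in table.index and a.direction in table.columns:
            table.loc[a.group, a.direction] += 1
    return table


# ---------------------------------------------------------------------------
# Tab-delimited I/O
# ---------------------------------------------------------------------------

def _call_from_row(row, cond: str) -> ConditionCall:
    modulated = str(row[f"modulated_{cond}"]).lower() in ("1", "true", "yes")
    if not modulated:
        return ConditionCall(False)
    return ConditionCall(True, row[f"dir_{cond}"], float(row[f"fc_{cond}"]))


def read_calls_table(path) -> list[GeneRegulationCalls]:
    """Read gene, then (modulated, dir, fc) triples for si1/si2/si12.
    Unmodulated conditions may leave dir/fc blank or NA."""
    df = pd.read_csv(path, sep="\t")
    required = ["gene"] + [
        f"{p}_{c}" for c in CONDITIONS for p in ("modulated", "dir", "fc")
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        GeneRegulationCalls(
            str(row["gene"]),
            _call_from_row(row, "si1"),
            _call_from_row(row, "si2"),
            _call_from_row(row, "si12"),
        )
        for _, row in df.iterrows()
    ]


def write_assignments(assignments: list[GroupAssignment], path) -> None:
    pd.DataFrame(
        {
            "gene": [a.gene for a in assignments],
            "group": [a.group for a in assignments],
            "direction": [a.direction or "NA" for a in assignments],
            "discordant": [int(a.discordant) for a in assignments],
            "both_nonadditive": [int(a.both_nonadditive) for a in assignments],
            "max_abs_fc": [a.max_abs_fc for a in assignments],
        }
    ).to_csv(path, sep="\t", index=False)
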