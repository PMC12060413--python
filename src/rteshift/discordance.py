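"""Locus-level discordant transcript classification.

A locus is discordant in a tumour-vs-normal comparison when it produces at
least one significantly upregulated and at least one significantly
downregulated transcript. The discordant transcripts of a comparison are
all the differentially expressed members (both directions) of discordant
loci; the discordant fraction is their share of all DE transcripts.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .intervals import ValidationError


@dataclass
class DiscordanceResult:
    """Per-comparison discordance summary."""

    cancer_type: str
    n_de: int
    n_disc: int
    n_disc_up: int
    n_disc_down: int
    discordant_loci: set[str]
    per_locus: dict[str, tuple[set[str], set[str]]] = field(default_factory=dict)

    @property
    def discordant_fraction(self) -> float:
        """n_disc / n_de; NA (nan) when there are no DE transcripts."""
        return math.nan if self.n_de == 0 else self.n_disc / self.n_de

    @property
    def discordant_transcripts(self) -> set[str]:
        out: set[str] = set()
        for locus in self.discordant_loci:
            up, down = self.per_locus[locus]
            out |= up | down
        return out


def find_discordant(
    de: pd.DataFrame,
    tx2locus: Mapping[str, str],
    cancer_type: str = "",
) -> DiscordanceResult:
    """Classify loci by the direction calls of their transcripts.

    ``de`` is the differential_transcripts output (indexed by transcript,
    with a ``direction`` column). Every DE transcript must be present in
    the transcript -> locus map.
    """
    de_calls = de[de["direction"] != "ns"]
    missing = [t for t in de_calls.index if t not in tx2locus]
    if missing:
        raise ValidationError(f"DE transcripts missing from locus map: {missing[:5]}")
    per_locus: dict[str, tuple[set[str], set[str]]] = {}
    for tid, direction in de_calls["direction"].items():
        locus = tx2locus[tid]
        up, down = per_locus.setdefault(locus, (set(), set()))
        (up if direction == "up" else down).add(tid)
    discordant = {loc for loc, (up, down) in per_locus.items() if up and down}
    n_up = sum(len(per_locus[loc][0]) for loc in discordant)
    n_down = sum(len(per_locus[loc][1]) for loc in discordant)
    return DiscordanceResult(
        cancer_type=cancer_type,
        n_de=len(de_calls),
        n_disc=n_up + n_down,
        n_disc_up=n_up,
        n_disc_down=n_down,
        discordant_loci=discordant,
        per_locus=per_locus,
    )


def cross_cancer_sharing(results: Sequence[DiscordanceResult]) -> dict[str, float]:
    """Fraction of each type's discordant loci also discordant elsewhere.

    For each cancer type: |its discordant loci intersected with the union
    of the other types' discordant loci| / |its discordant loci|; NA (nan)
    for a type without discordant loci.
    """
    if len(results) < 2:
        raise ValidationError("cross_cancer_sharing requires >= 2 cancer types")
    sharing: dict[str, float] = {}
    for i, res in enumerate(results):
        others: set[str] = set()
        for j, other in enumerate(results):
            if j != i:
                others |= other.discordant_loci
        if not res.discordant_loci:
            sharing[res.cancer_type] = math.nan
        else:
            sharing[res.cancer_type] = len(res.discordant_loci & others) / len(
                res.discordant_loci
            )
    return sharing


def write_discordance_report(result: DiscordanceResult, path) -> None:
    """TSV report: one row per locus with DE members (locus, n_up, n_down, flag)."""
    with open(path, "w") as fh:
        fh.write("locus_id\tn_up\tn_down\tdiscordant\n")
        for locus in sorted(result.per_locus):
            up, down = result.per_locus[locus]
            flag = "yes" if locus in result.discordant_loci else "no"
            fh.write(f"{locus}\t{len(up)}\t{len(down)}\t{flag}\n")


def write_sharing_matrix(sharing: Mapping[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("cancer_type\tsharing_fraction\n")
        for ct in sorted(sharing):
            v = sharing[ct]
            fh.write(f"{ct}\t{'NA' if math.isnan(v) else f'{v:.6g}'}\n")
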