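"""Repeat-subgroup enrichment among discordant transcripts.

Fisher's exact test on the 2x2 table (discordant vs not) x (subgroup vs
not), with the whole transcriptome as background, Bonferroni-Holm
family-wise correction across subgroups, and fold-enrichment defined as the
subgroup's frequency among discordant transcripts over its frequency in the
entire transcriptome.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Set

from .intervals import ValidationError

_TWO_SIDED_TOL = 1e-7  # relative tolerance for probability ties


@dataclass
class EnrichmentResult:
    """One subgroup's 2x2 enrichment result.

    a = discordant & subgroup, b = discordant & not, c = non-discordant &
    subgroup, d = non-discordant & not.
    """

    subgroup: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    fold_enrichment: float
    p: float
    p_holm: float


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_exact(a: int, b: int, c: int, d: int, sided: str = "two") -> tuple[float, float]:
    """Fisher's exact test for a 2x2 table.

    Two-sided p sums hypergeometric probabilities of all tables with the
    observed margins no more probable than the observed one (minimum-
    likelihood criterion, the MATLAB/R convention); "greater" sums tables
    with cell a >= observed. Odds ratio is the sample odds ratio ad/bc
    (inf when bc = 0 and ad > 0, nan when both products are 0).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValidationError(f"counts must be non-negative integers, got {(a, b, c, d)}")
    if sided not in ("two", "greater"):
        raise ValidationError(f"sided must be 'two' or 'greater', got {sided!r}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    ad, bc = a * d, b * c
    if ad == 0 and bc == 0:
        odds = math.nan
    elif bc == 0:
        odds = math.inf
    else:
        odds = ad / bc
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return odds, 1.0  # single attainable table
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = _log_binom(n, c1)
    logp = [_log_binom(r1, k) + _log_binom(r2, c1 - k) - denom for k in range(lo, hi + 1)]
    p_obs = math.exp(logp[a - lo])
    if sided == "greater":
        p = sum(math.exp(lp) for k, lp in zip(range(lo, hi + 1), logp) if k >= a)
    else:
        cutoff = p_obs * (1.0 + _TWO_SIDED_TOL)
        p = sum(math.exp(lp) for lp in logp if math.exp(lp) <= cutoff)
    return odds, min(1.0, p)


def holm_adjust(pvals: Sequence[float]) -> list[float]:
    """Bonferroni-Holm step-down adjustment, order restored to the input."""
    m = len(pvals)
    for p in pvals:
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"p-value out of [0,1]: {p}")
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, pvals[idx] * (m - rank)))
        adjusted[idx] = running
    return adjusted


def rte_subgroup_enrichment(
    discordant: Set[str] | Iterable[str],
    universe: Set[str] | Iterable[str],
    tx_subgroups: Mapping[str, Set[str] | Iterable[str]],
    subgroups: Sequence[str] | None = None,
) -> list[EnrichmentResult]:
    """Per-subgroup Fisher enrichment of discordant transcripts vs the
    whole transcriptome.

    ``tx_subgroups`` maps a transcript to the set of repeat subgroups it
    touches (a transcript may carry several exonised elements); membership
    is counted once per subgroup per transcript. Holm correction is applied
    across all tested subgroups.
    """
    discordant = set(discordant)
    universe = set(universe)
    if not discordant <= universe:
        extra = sorted(discordant - universe)[:5]
        raise ValidationError(f"discordant transcripts outside universe, e.g. {extra}")
    labels: dict[str, set[str]] = {
        t: set(tx_subgroups.get(t, ())) for t in universe
    }
    if subgroups is None:
        present: set[str] = set()
        for s in labels.values():
            present |= s
        subgroups = sorted(present)
    n = len(universe)
    n_disc = len(discordant)
    results: list[EnrichmentResult] = []
    for sg in subgroups:
        members = {t for t, s in labels.items() if sg in s}
        a = len(members & discordant)
        b = n_disc - a
        c = len(members) - a
        d = n - n_disc - c
        odds, p = fisher_exact(a, b, c, d, sided="two")
        disc_freq = a / (a + b) if (a + b) else math.nan
        bg_freq = (a + c) / n if n else math.nan
        fold = math.nan if not bg_freq or math.isnan(disc_freq) else disc_freq / bg_freq
        results.append(EnrichmentResult(sg, a, b, c, d, odds, fold, p, p_holm=p))
    adj = holm_adjust([r.p for r in results])
    for r, q in zip(results, adj):
        r.p_holm = q
    return results


def write_enrichment_table(results: Sequence[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("subgroup\ta\tb\tc\td\tfold_enrichment\todds_ratio\tp\tp_holm\n")
        for r in results:
            fh.write(
                f"{r.subgroup}\t{r.a}\t{r.b}\t{r.c}\t{r.d}\t"
                f"{r.fold_enrichment:.6g}\t{r.odds_ratio:.6g}\t{r.p:.6g}\t{r.p_holm:.6g}\n"
            )
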