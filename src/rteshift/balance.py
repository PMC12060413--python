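"""Per-sample isoform-balance metrics and sample stratification.

The quantities mirrored here are the canonical fraction of a gene's total
expression (canonical / (canonical + sum of alternative isoform groups)),
alternative-to-canonical ratios, and low/high expression strata used to
split cohorts for group comparisons and survival analysis.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Set

import numpy as np
import pandas as pd

from .expression import QuantMatrix
from .intervals import ValidationError
from . import stats as stats_core


@dataclass
class Stratification:
    """Low/high sample labels under a recorded rule."""

    rule: str
    labels: pd.Series  # sample_id -> "low" | "high"
    threshold: float

    @property
    def counts(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()


def balance_metrics(
    qm: QuantMatrix,
    locus_id: str,
    canonical_ids: Set[str] | Sequence[str],
    alt_groups: Mapping[str, Set[str] | Sequence[str]],
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-sample isoform balance for one locus.

    Group TPM is the sum over member transcripts. canonical_fraction =
    canonical / (canonical + sum of alt groups); ratio_<name> =
    alt / canonical. Zero denominators give NA (never inf); a positive
    ``pseudocount`` is added to denominators instead.

    Returns a DataFrame indexed by sample with columns canonical_tpm,
    alt_<name>_tpm, canonical_fraction, ratio_<name>.
    """
    canonical_ids = list(canonical_ids)
    groups = {name: list(ids) for name, ids in alt_groups.items()}
    all_ids = canonical_ids + [t for ids in groups.values() for t in ids]
    if len(set(all_ids)) != len(all_ids):
        raise ValidationError("canonical and alternative id sets must be disjoint")
    unknown = set(all_ids) - set(qm.transcript_ids)
    if unknown:
        raise ValidationError(f"unknown transcript ids: {sorted(unknown)[:5]}")

    canonical = qm.tpm.loc[canonical_ids].sum(axis=0)
    out = pd.DataFrame({"locus_id": locus_id, "canonical_tpm": canonical})
    alt_total = pd.Series(0.0, index=qm.tpm.columns)
    for name, ids in groups.items():
        alt = qm.tpm.loc[ids].sum(axis=0)
        out[f"alt_{name}_tpm"] = alt
        alt_total = alt_total + alt
    denom = canonical + alt_total + pseudocount
    out["canonical_fraction"] = np.where(denom > 0, canonical / denom, np.nan)
    ratio_denom = canonical + pseudocount
    for name in groups:
        out[f"ratio_{name}"] = np.where(
            ratio_denom > 0, out[f"alt_{name}_tpm"] / ratio_denom, np.nan
        )
    out.index.name = "sample_id"
    return out


def stratify(values: Mapping[str, float] | pd.Series, rule: str = "fixed_tpm", param: float = 1.0) -> Stratification:
    """Split samples into low/high expression strata.

    Rules: ``median`` (threshold = cohort median), ``tertile_upper``
    (upper tertile is high), ``fixed_tpm`` (threshold = ``param``, default
    1.0 TPM — an expression-detectability cut for RTE-driven transcripts),
    ``quantile`` (threshold = the ``param`` quantile). Ties at the
    threshold are labelled "low".
    """
    s = pd.Series(values, dtype=float)
    if s.empty:
        raise ValidationError("stratify requires non-empty values")
    if rule == "median":
        threshold = float(s.median())
        if s.nunique() == 1:
            import warnings

            warnings.warn("all values identical under median rule; all samples 'low'")
    elif rule == "tertile_upper":
        threshold = float(s.quantile(2.0 / 3.0))
    elif rule == "fixed_tpm":
        threshold = float(param)
    elif rule == "quantile":
        if not 0.0 < param < 1.0:
            raise ValidationError("quantile parameter must lie in (0,1)")
        threshold = float(s.quantile(param))
    else:
        raise ValidationError(f"unknown stratification rule {rule!r}")
    labels = pd.Series(np.where(s > threshold, "high", "low"), index=s.index)
    rule_desc = f"{rule}({param:g})" if rule in ("fixed_tpm", "quantile") else rule
    return Stratification(rule=rule_desc, labels=labels, threshold=threshold)


def correlate_balance(
    x: Mapping[str, float] | pd.Series,
    y: Mapping[str, float] | pd.Series,
    method: str = "linregress",
) -> tuple[float, float]:
    """Correlate two per-sample metrics over their shared non-NA samples.

    ``pearson`` and ``spearman`` return (coefficient, two-sided p);
    ``linregress`` returns the Pearson coefficient with the p-value of the
    regression slope t-test.
    """
    xs = pd.Series(x, dtype=float)
    ys = pd.Series(y, dtype=float)
    joined = pd.concat([xs, ys], axis=1, keys=["x", "y"]).dropna()
    if len(joined) < 3:
        raise ValidationError("correlate_balance requires >= 3 paired samples")
    xv, yv = joined["x"].to_numpy(), joined["y"].to_numpy()
    if method == "pearson":
        from scipy.stats import pearsonr

        r, p = pearsonr(xv, yv)
        return float(r), float(p)
    if method == "spearman":
        from scipy.stats import spearmanr

        r, p = spearmanr(xv, yv)
        return float(r), float(p)
    if method == "linregress":
        slope, _, r2, p = stats_core.linregress(xv, yv)
        r = math.copysign(math.sqrt(max(r2, 0.0)), slope)
        return r, p
    raise ValidationError(f"unknown method {method!r}")


def write_balance_table(balance: pd.DataFrame, path) -> None:
    balance.to_csv(path, sep="\t", float_format="%.6g")


def write_strata_table(strat: Stratification, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# rule={strat.rule} threshold={strat.threshold:.6g}\n")
        fh.write("sample_id\tstratum\n")
        for sample, label in strat.labels.items():
            fh.write(f"{sample}\t{label}\n")
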