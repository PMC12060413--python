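"""Quantification tables and differential transcript expression.

The quantification unit is TPM (transcripts per million). Differential
expression between two sample groups follows the selection used throughout
the analysis: linear fold-change on pseudocounted TPM means, a two-sided
Welch t-test on log2(TPM + pseudocount), Benjamini-Hochberg q-values, and
direction calls at >= 1.5 fold-change with p <= 0.05 and q <= 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .intervals import ValidationError


@dataclass
class QuantMatrix:
    """Transcripts x samples TPM matrix (pandas-backed)."""

    tpm: pd.DataFrame  # rows: transcript_ids, columns: sample_ids

    def __post_init__(self) -> None:
        if self.tpm.index.has_duplicates:
            raise ValidationError("duplicate transcript ids")
        if self.tpm.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if (self.tpm.values < 0).any():
            raise ValidationError("negative TPM values")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tpm.columns)


def read_quant(path) -> QuantMatrix:
    """Read a wide transcript x sample TSV (first column = transcript id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric TPM in {path}: {exc}") from None
    return QuantMatrix(values)


def read_quant_files(
    paths: dict[str, "str | Path"],
    name_col: str = "Name",
    tpm_col: str = "TPM",
    zero_fill: bool = False,
) -> QuantMatrix:
    """Assemble a matrix from per-sample quantification files.

    ``paths`` maps sample id -> file. Files are tab-separated with at least
    a transcript-name column and a TPM column (Salmon-style ``quant.sf``
    headers are the default). Transcripts missing from a sample are an
    error unless ``zero_fill`` is set, in which case they become 0.0.
    """
    columns: dict[str, pd.Series] = {}
    for sample, p in paths.items():
        df = pd.read_csv(p, sep="\t")
        if name_col not in df.columns or tpm_col not in df.columns:
            raise ValidationError(f"{p}: expected columns {name_col!r} and {tpm_col!r}")
        s = df.set_index(name_col)[tpm_col].astype(float)
        if s.index.has_duplicates:
            raise ValidationError(f"{p}: duplicate transcript ids")
        columns[sample] = s
    mat = pd.DataFrame(columns)
    if mat.isna().any().any():
        if zero_fill:
            mat = mat.fillna(0.0)
        else:
            missing = mat.index[mat.isna().any(axis=1)][:5]
            raise ValidationError(
                f"transcripts missing from some samples (e.g. {list(missing)}); "
                "pass zero_fill=True to fill with 0"
            )
    return QuantMatrix(mat)


def read_sample_meta(path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, condition, cancer_type,
    optional stage / os_time / os_event)."""
    meta = pd.read_csv(path, sep="\t")
    if "sample_id" not in meta.columns:
        raise ValidationError("metadata requires a sample_id column")
    meta = meta.set_index("sample_id")
    if "os_time" in meta.columns:
        bad = meta["os_time"].dropna() <= 0
        if bad.any():
            raise ValidationError("os_time must be positive where present")
    return meta


def bh_qvalues(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order restored to the input."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def differential_transcripts(
    qm: QuantMatrix,
    group_a: Iterable[str],
    group_b: Iterable[str],
    pseudocount: float = 0.01,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    alpha_q: float = 0.05,
) -> pd.DataFrame:
    """Per-transcript differential expression of group A vs group B.

    fc = (mean_A + pc) / (mean_B + pc) on linear TPM; p from a two-sided
    Welch t-test on log2(TPM + pc); q by Benjamini-Hochberg across all
    tested transcripts. direction is "up" when fc >= fc_threshold with
    p <= alpha and q <= alpha_q, "down" symmetrically with 1/fc, else "ns".
    Zero-variance rows: equal means give p = 1; unequal means with no
    within-group variance give p = 0 (flagged in the ``degenerate`` column).

    Returns a DataFrame indexed by transcript_id with columns
    fc, log2fc, p, q, direction, degenerate.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValidationError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs >= 2 samples")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    missing = (set(group_a) | set(group_b)) - set(qm.sample_ids)
    if missing:
        raise ValidationError(f"unknown sample ids: {sorted(missing)[:5]}")

    a = qm.tpm[group_a].to_numpy(dtype=float)
    b = qm.tpm[group_b].to_numpy(dtype=float)
    fc = (a.mean(axis=1) + pseudocount) / (b.mean(axis=1) + pseudocount)

    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    na, nb = la.shape[1], lb.shape[1]
    ma, mb = la.mean(axis=1), lb.mean(axis=1)
    va, vb = la.var(axis=1, ddof=1), lb.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = np.where(np.isfinite(t), 2.0 * _sps.t.sf(np.abs(t), np.where(df > 0, df, 1)), 1.0)
    p = np.minimum(p, 1.0)
    degenerate = se2 == 0
    equal_means = np.isclose(ma, mb)
    p[degenerate & equal_means] = 1.0
    p[degenerate & ~equal_means] = 0.0

    q = bh_qvalues(p)
    direction = np.full(p.shape, "ns", dtype=object)
    direction[(fc >= fc_threshold) & (p <= alpha) & (q <= alpha_q)] = "up"
    direction[(1.0 / fc >= fc_threshold) & (p <= alpha) & (q <= alpha_q)] = "down"

    return pd.DataFrame(
        {
            "fc": fc,
            "log2fc": np.log2(fc),
            "p": p,
            "q": q,
            "direction": direction,
            "degenerate": degenerate & ~equal_means,
        },
        index=pd.Index(qm.transcript_ids, name="transcript_id"),
    )


def write_de_table(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", float_format="%.6g")
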