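"""Synthetic dataset generator with ground truth.

Emits a toy annotation (GTF), repeat annotation (RepeatMasker ``.out``),
TPM quantification matrix and sample metadata with survival, structured so
that every pipeline stage has a known answer: each locus carries a
canonical isoform and one RTE-derived isoform (exonised terminal exon or
RTE-initiated antisense transcript); a configurable fraction of loci is
discordant (RTE isoform up, canonical down, in tumours); repeat subgroups
are placed in discordant loci at frequencies solved analytically so the
expected measured fold-enrichment equals the configured fold; expression
is log-normal around condition means; and survival times are exponential
with the hazard multiplied by the configured hazard ratio for tumours in
the high-RTE stratum.

Identical seeds yield byte-identical output files.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .repeats import RepeatFeature, write_repeatmasker
from .intervals import GenomicInterval, ValidationError

#: representative family/class per subgroup for emitted repeat rows
_SUBGROUP_FAMILIES: dict[str, tuple[str, str]] = {
    "Alu": ("AluSx", "SINE/Alu"),
    "MIR": ("MIR3", "SINE/MIR"),
    "L1": ("L1PA2", "LINE/L1"),
    "L2": ("L2a", "LINE/L2"),
    "ERV/LTR": ("THE1A", "LTR/ERVL-MaLR"),
    "SVA": ("SVA_D", "Retroposon/SVA"),
}

#: background subgroup frequencies for the RTE isoform's element
DEFAULT_BASE_FREQ: dict[str, float] = {
    "Alu": 0.10,
    "MIR": 0.10,
    "L1": 0.15,
    "L2": 0.10,
    "ERV/LTR": 0.45,
    "SVA": 0.10,
}


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults are the standard study conditions."""

    n_loci: int = 2000
    p_disc: float = 0.3
    fc_up: float = 4.0
    fc_down: float = 0.25
    rte_enrichment: dict[str, float] = field(default_factory=lambda: {"Alu": 2.5})
    base_subgroup_freq: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_FREQ))
    n_tumour: int = 30
    n_normal: int = 30
    noise_sigma: float = 0.25
    baseline_logtpm_range: tuple[float, float] = (3.0, 7.0)
    rte_baseline_logtpm_range: tuple[float, float] = (2.0, 5.0)
    concordant_fraction: float = 0.2
    antisense_fraction: float = 0.3
    mode: str = "generic"  # or "antisense_suppression"
    rte_coupling: float = 2.0
    antisense_coupling: float = 1.0
    baseline_hazard: float = 0.1
    hr_true: float = 2.0
    censor_rate: float = 0.2
    cancer_type: str = "SYNTH"
    chrom: str = "chrS1"
    locus_span: int = 9000
    locus_spacing: int = 20000
    chrom_length: int = 50_000_000
    discordant_locus_indices: Sequence[int] | None = None
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.p_disc <= 1.0):
            raise ValidationError("p_disc must lie in [0,1]")
        if self.fc_up < 1.5 or self.fc_down > 1.0 / 1.5:
            raise ValidationError("fc_up must be >= 1.5 and fc_down <= 1/1.5")
        if self.hr_true <= 0:
            raise ValidationError("hr_true must be positive")
        if self.mode not in ("generic", "antisense_suppression"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.n_loci * self.locus_spacing > self.chrom_length:
            raise ValidationError(
                f"layout overflow: {self.n_loci} loci x {self.locus_spacing} bp "
                f"exceed chromosome length {self.chrom_length}"
            )
        for sg, phi in self.rte_enrichment.items():
            if phi < 1.0:
                raise ValidationError(f"enrichment fold for {sg} must be >= 1")
            if phi * self.p_disc >= 1.0 and self.p_disc > 0:
                raise ValidationError(
                    f"infeasible enrichment: fold {phi} x p_disc {self.p_disc} >= 1"
                )


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for recovery tests."""

    discordant_loci: set[str]
    direction: dict[str, str]  # transcript_id -> up | down | ns
    subgroup_expected_fold: dict[str, float]
    sample_stratum: dict[str, str]  # tumour sample -> low | high
    hr_true: float
    n_loci: int
    locus_ids: list[str]
    tx_subgroup: dict[str, str]  # RTE isoform -> subgroup


def _solve_discordant_freqs(cfg: SyntheticConfig) -> dict[str, float]:
    """Subgroup frequencies inside discordant loci giving expected measured
    fold-enrichment equal to the configured fold.

    fold = q_d / (p_disc * q_d + (1 - p_disc) * q_n)  =>
    q_d = fold * (1 - p_disc) * q_n / (1 - fold * p_disc).
    """
    q_n = cfg.base_subgroup_freq
    if abs(sum(q_n.values()) - 1.0) > 1e-9:
        raise ValidationError("base subgroup frequencies must sum to 1")
    if cfg.p_disc == 0:
        return dict(q_n)
    q_d: dict[str, float] = {}
    for sg, phi in cfg.rte_enrichment.items():
        if sg not in q_n:
            raise ValidationError(f"enriched subgroup {sg!r} missing from base frequencies")
        q_d[sg] = phi * (1.0 - cfg.p_disc) * q_n[sg] / (1.0 - phi * cfg.p_disc)
    mass = sum(q_d.values())
    if mass > 1.0:
        raise ValidationError("enrichment configuration demands > 100% subgroup mass")
    rest_base = sum(v for sg, v in q_n.items() if sg not in q_d)
    scale = (1.0 - mass) / rest_base if rest_base > 0 else 0.0
    for sg, v in q_n.items():
        if sg not in q_d:
            q_d[sg] = v * scale
    return q_d


def simulate_survival(
    n: int,
    hr_true: float,
    baseline_hazard: float = 0.1,
    censor_rate: float = 0.0,
    p_high: float = 0.5,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Exponential survival times for a binary-stratum cohort.

    High-stratum subjects (probability ``p_high``) have hazard
    ``baseline_hazard * hr_true``. Independent exponential censoring is
    calibrated so baseline subjects are censored with probability
    ``censor_rate``. Returns columns time, event, group.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    high = rng.random(n) < p_high
    hazard = baseline_hazard * np.where(high, hr_true, 1.0)
    t = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        lam_c = baseline_hazard * censor_rate / (1.0 - censor_rate)
        c = rng.exponential(1.0 / lam_c, size=n)
    else:
        c = np.full(n, np.inf)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return pd.DataFrame(
        {"time": time, "event": event, "group": np.where(high, "high", "low")}
    )


def generate(config: SyntheticConfig, outdir) -> tuple[dict[str, Path], SyntheticTruth]:
    """Write the synthetic dataset and return (file paths, truth ledger).

    Emitted files: ``annotation.gtf``, ``repeats.out``, ``quant.tsv``,
    ``metadata.tsv``, ``truth.tsv``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    n = config.n_loci
    subgroups = sorted(config.base_subgroup_freq)
    q_n = np.array([config.base_subgroup_freq[s] for s in subgroups])
    q_d_map = _solve_discordant_freqs(config)
    q_d = np.array([q_d_map[s] for s in subgroups])

    # --- locus roles ---------------------------------------------------
    if config.discordant_locus_indices is not None:
        disc_mask = np.zeros(n, dtype=bool)
        disc_mask[list(config.discordant_locus_indices)] = True
    else:
        n_disc = int(round(config.p_disc * n))
        disc_idx = rng.choice(n, size=n_disc, replace=False)
        disc_mask = np.zeros(n, dtype=bool)
        disc_mask[disc_idx] = True
    conc_mask = np.zeros(n, dtype=bool)
    non_disc = np.where(~disc_mask)[0]
    if non_disc.size:
        n_conc = int(round(config.concordant_fraction * non_disc.size))
        conc_mask[rng.choice(non_disc, size=n_conc, replace=False)] = True

    subgroup_idx = np.empty(n, dtype=int)
    for i in range(n):
        probs = q_d if disc_mask[i] else q_n
        subgroup_idx[i] = rng.choice(len(subgroups), p=probs)
    antisense = rng.random(n) < config.antisense_fraction

    # --- samples -------------------------------------------------------
    tumour_ids = [f"T{i+1:03d}" for i in range(config.n_tumour)]
    normal_ids = [f"N{i+1:03d}" for i in range(config.n_normal)]
    z = rng.standard_normal(config.n_tumour)  # latent RTE activity per tumour
    stratum = np.where(z > 0, "high", "low")

    # --- annotation + repeats ------------------------------------------
    locus_ids: list[str] = []
    gtf_lines: list[str] = []
    repeat_rows: list[RepeatFeature] = []
    tx_subgroup: dict[str, str] = {}
    chrom = config.chrom
    for i in range(n):
        s = i * config.locus_spacing
        locus_ids.append(f"{chrom}:{s}-{s + config.locus_span}")
        gid, can, rte = f"G{i:05d}", f"T{i:05d}c", f"T{i:05d}r"
        sg = subgroups[subgroup_idx[i]]
        tx_subgroup[rte] = sg

        def exon(a: int, b: int, tid: str, strand: str) -> str:
            return (
                f"{chrom}\trteshift_sim\texon\t{s + a + 1}\t{s + b}\t.\t{strand}\t.\t"
                f'gene_id "{gid}"; transcript_id "{tid}";'
            )

        # canonical: two exons spanning the locus
        gtf_lines.append(exon(0, 500, can, "+"))
        gtf_lines.append(exon(8000, config.locus_span, can, "+"))
        if antisense[i]:
            # RTE-initiated antisense transcript starting inside the element
            gtf_lines.append(exon(2500, 3200, rte, "-"))
        else:
            # exonised terminal exon inside the element
            gtf_lines.append(exon(0, 500, rte, "+"))
            gtf_lines.append(exon(3000, 3300, rte, "+"))

        family, rclass = _SUBGROUP_FAMILIES[sg]
        if sg == "ERV/LTR":
            # provirus: LTR / internal / LTR fragments sharing an rm_id
            for (a, b), fam in (
                ((3000, 3100), "LTR2B"),
                ((3100, 3250), "HERVE-int"),
                ((3250, 3300), "LTR2B"),
            ):
                repeat_rows.append(
                    RepeatFeature(
                        GenomicInterval(chrom, s + a, s + b, "+"),
                        family=fam,
                        repeat_class="LTR/ERV1",
                        rm_id=i + 1,
                        divergence_pct=10.0,
                    )
                )
        else:
            repeat_rows.append(
                RepeatFeature(
                    GenomicInterval(chrom, s + 3000, s + 3300, "+"),
                    family=family,
                    repeat_class=rclass,
                    rm_id=i + 1,
                    divergence_pct=15.0,
                )
            )

    gtf_path = outdir / "annotation.gtf"
    gtf_path.write_text("\n".join(gtf_lines) + "\n")
    rmsk_path = outdir / "repeats.out"
    write_repeatmasker(repeat_rows, rmsk_path)

    # --- expression -----------------------------------------------------
    lo, hi = config.baseline_logtpm_range
    rlo, rhi = config.rte_baseline_logtpm_range
    base_can = rng.uniform(lo, hi, size=n)
    base_rte = rng.uniform(rlo, rhi, size=n)

    lfc_up = math.log2(config.fc_up)
    lfc_down = math.log2(config.fc_down)
    can_shift = np.where(disc_mask, lfc_down, np.where(conc_mask, lfc_up, 0.0))
    rte_shift = np.where(disc_mask | conc_mask, lfc_up, 0.0)

    n_t, n_n = config.n_tumour, config.n_normal
    mu_can_t = base_can[:, None] + can_shift[:, None] + np.zeros((1, n_t))
    mu_rte_t = base_rte[:, None] + rte_shift[:, None] + np.zeros((1, n_t))
    coupled = disc_mask[:, None].astype(float)
    mu_rte_t = mu_rte_t + coupled * config.rte_coupling * z[None, :]
    if config.mode == "antisense_suppression":
        mu_can_t = mu_can_t - coupled * config.antisense_coupling * z[None, :]

    sig = config.noise_sigma
    tpm_can_t = 2.0 ** (mu_can_t + rng.normal(0.0, sig, size=(n, n_t)))
    tpm_can_n = 2.0 ** (base_can[:, None] + rng.normal(0.0, sig, size=(n, n_n)))
    tpm_rte_t = 2.0 ** (mu_rte_t + rng.normal(0.0, sig, size=(n, n_t)))
    tpm_rte_n = 2.0 ** (base_rte[:, None] + rng.normal(0.0, sig, size=(n, n_n)))

    tids = [f"T{i:05d}c" for i in range(n)] + [f"T{i:05d}r" for i in range(n)]
    mat = np.vstack(
        [
            np.hstack([tpm_can_t, tpm_can_n]),
            np.hstack([tpm_rte_t, tpm_rte_n]),
        ]
    )
    quant = pd.DataFrame(mat, index=tids, columns=tumour_ids + normal_ids)
    quant.index.name = "transcript_id"
    quant_path = outdir / "quant.tsv"
    quant.to_csv(quant_path, sep="\t", float_format="%.4f")

    # --- survival + metadata -------------------------------------------
    hazard = config.baseline_hazard * np.where(stratum == "high", config.hr_true, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        lam_c = config.baseline_hazard * config.censor_rate / (1.0 - config.censor_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=n_t)
    else:
        t_cens = np.full(n_t, np.inf)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)
    stages = rng.choice(["I", "II", "III", "IV"], size=n_t, p=[0.45, 0.15, 0.25, 0.15])

    meta_path = outdir / "metadata.tsv"
    with open(meta_path, "w") as fh:
        fh.write("sample_id\tcondition\tcancer_type\tstage\tos_time\tos_event\n")
        for k, sid in enumerate(tumour_ids):
            fh.write(
                f"{sid}\ttumour\t{config.cancer_type}\t{stages[k]}\t"
                f"{os_time[k]:.4f}\t{os_event[k]}\n"
            )
        for sid in normal_ids:
            fh.write(f"{sid}\tnormal\t{config.cancer_type}\t\t\t\n")

    # --- truth ledger ---------------------------------------------------
    direction: dict[str, str] = {}
    for i in range(n):
        if disc_mask[i]:
            direction[f"T{i:05d}c"] = "down"
            direction[f"T{i:05d}r"] = "up"
        elif conc_mask[i]:
            direction[f"T{i:05d}c"] = "up"
            direction[f"T{i:05d}r"] = "up"
        else:
            direction[f"T{i:05d}c"] = "ns"
            direction[f"T{i:05d}r"] = "ns"
    expected_fold = {
        sg: (
            q_d_map[sg]
            / (config.p_disc * q_d_map[sg] + (1 - config.p_disc) * config.base_subgroup_freq[sg])
            if config.p_disc > 0
            else 1.0
        )
        for sg in subgroups
    }
    truth = SyntheticTruth(
        discordant_loci={locus_ids[i] for i in np.where(disc_mask)[0]},
        direction=direction,
        subgroup_expected_fold=expected_fold,
        sample_stratum={sid: str(stratum[k]) for k, sid in enumerate(tumour_ids)},
        hr_true=config.hr_true,
        n_loci=n,
        locus_ids=locus_ids,
        tx_subgroup=tx_subgroup,
    )
    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write(f"# hr_true={config.hr_true} p_disc={config.p_disc} seed={config.seed}\n")
        fh.write("record\tkey\tvalue\n")
        for i in range(n):
            fh.write(f"locus\t{locus_ids[i]}\t{'discordant' if disc_mask[i] else 'other'}\n")
        for tid in sorted(direction):
            fh.write(f"direction\t{tid}\t{direction[tid]}\n")
        for sg in subgroups:
            fh.write(f"expected_fold\t{sg}\t{expected_fold[sg]:.6g}\n")
        for sid in tumour_ids:
            fh.write(f"stratum\t{sid}\t{truth.sample_stratum[sid]}\n")

    paths = {
        "gtf": gtf_path,
        "rmsk": rmsk_path,
        "quant": quant_path,
        "metadata": meta_path,
        "truth": truth_path,
    }
    return paths, truth


def truth_report(
    truth: SyntheticTruth,
    called_discordant_loci: set[str],
    alu_fold: float | None = None,
    hr_estimate: float | None = None,
) -> dict[str, float]:
    """Recovery metrics comparing pipeline calls against the truth ledger."""
    unknown = called_discordant_loci - set(truth.locus_ids)
    if unknown:
        raise ValidationError(f"called loci unknown to truth: {sorted(unknown)[:5]}")
    n_true = len(truth.discordant_loci)
    n_called = len(called_discordant_loci)
    tp = len(called_discordant_loci & truth.discordant_loci)
    report = {
        "recovery": tp / n_true if n_true else math.nan,
        "false_discovery": (n_called - tp) / n_called if n_called else 0.0,
        "called_fraction": n_called / truth.n_loci,
    }
    if alu_fold is not None:
        report["alu_fold_error"] = alu_fold - truth.subgroup_expected_fold.get("Alu", math.nan)
    if hr_estimate is not None:
        report["hr_error"] = hr_estimate - truth.hr_true
    return report
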