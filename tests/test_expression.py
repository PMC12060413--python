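"""Quantification I/O, BH q-values and differential transcript calls."""
import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from rteshift.expression import (
    QuantMatrix,
    bh_qvalues,
    differential_transcripts,
    read_quant,
    read_quant_files,
)
from rteshift.intervals import ValidationError


def make_qm(a, b, n_extra=0, rng=None):
    """Matrix with one transcript of interest plus background rows."""
    rng = rng or np.random.default_rng(0)
    rows = {"TX": list(a) + list(b)}
    for i in range(n_extra):
        rows[f"BG{i}"] = rng.lognormal(3, 0.3, size=len(a) + len(b))
    cols = [f"A{i}" for i in range(len(a))] + [f"B{i}" for i in range(len(b))]
    return QuantMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=cols))


class TestReaders:
    def test_wide_tsv(self, tmp_path):
        p = tmp_path / "q.tsv"
        p.write_text("transcript_id\tS1\tS2\nT1\t1.5\t2.0\nT2\t0\t3\n")
        qm = read_quant(p)
        assert qm.tpm.shape == (2, 2) and qm.tpm.loc["T1", "S2"] == 2.0

    def test_per_sample_files(self, tmp_path):
        for s, tpms in [("S1", (1, 2, 3)), ("S2", (4, 5, 6))]:
            (tmp_path / f"{s}.sf").write_text(
                "Name\tTPM\n" + "".join(f"T{i}\t{v}\n" for i, v in enumerate(tpms))
            )
        qm = read_quant_files({s: tmp_path / f"{s}.sf" for s in ("S1", "S2")})
        assert qm.tpm.shape == (3, 2)

    def test_missing_transcript_errors_unless_zero_fill(self, tmp_path):
        (tmp_path / "S1.sf").write_text("Name\tTPM\nT0\t1\nT1\t2\n")
        (tmp_path / "S2.sf").write_text("Name\tTPM\nT0\t1\n")
        paths = {"S1": tmp_path / "S1.sf", "S2": tmp_path / "S2.sf"}
        with pytest.raises(ValidationError):
            read_quant_files(paths)
        qm = read_quant_files(paths, zero_fill=True)
        assert qm.tpm.loc["T1", "S2"] == 0.0

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValidationError):
            QuantMatrix(pd.DataFrame({"S1": [-1.0]}, index=["T1"]))


class TestBH:
    def test_handworked_stepup(self):
        np.testing.assert_allclose(bh_qvalues([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_equal(self):
        assert bh_qvalues([1.0]) == pytest.approx([1.0])
        np.testing.assert_allclose(bh_qvalues([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_monotone_and_matches_statsmodels(self):
        rng = np.random.default_rng(3)
        p = rng.random(200)
        q = bh_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        np.testing.assert_allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_qvalues([0.5, 1.2])


class TestDifferential:
    def test_identical_groups_ns(self):
        qm = make_qm([5, 5, 5], [5, 5, 5], n_extra=5)
        de = differential_transcripts(qm, ["A0", "A1", "A2"], ["B0", "B1", "B2"])
        assert de.loc["TX", "fc"] == pytest.approx(1.0)
        assert de.loc["TX", "direction"] == "ns"

    def test_constant_groups_fold_change(self):
        qm = make_qm([30, 30, 30], [10, 10, 10], n_extra=5)
        de = differential_transcripts(qm, ["A0", "A1", "A2"], ["B0", "B1", "B2"])
        assert de.loc["TX", "fc"] == pytest.approx(30.01 / 10.01)
        assert de.loc["TX", "p"] == 0.0 and de.loc["TX", "degenerate"]

    def test_group_validation(self):
        qm = make_qm([1, 2, 3], [4, 5, 6])
        with pytest.raises(ValidationError):
            differential_transcripts(qm, ["A0", "A1"], ["A1", "B0"])
        with pytest.raises(ValidationError):
            differential_transcripts(qm, ["A0"], ["B0", "B1"])

    def test_swap_groups_flips_direction_and_inverts_fc(self):
        rng = np.random.default_rng(5)
        qm = make_qm(rng.lognormal(5, 0.2, 4), rng.lognormal(3, 0.2, 4), n_extra=20, rng=rng)
        a, b = ["A0", "A1", "A2", "A3"], ["B0", "B1", "B2", "B3"]
        d1 = differential_transcripts(qm, a, b)
        d2 = differential_transcripts(qm, b, a)
        np.testing.assert_allclose(d1["fc"], 1.0 / d2["fc"], rtol=1e-12)
        np.testing.assert_allclose(d1["p"], d2["p"], rtol=1e-9)
        flip = {"up": "down", "down": "up", "ns": "ns"}
        assert list(d1["direction"].map(flip)) == list(d2["direction"])

    def test_scaling_invariance_with_scaled_pseudocount(self):
        rng = np.random.default_rng(6)
        qm = make_qm(rng.lognormal(5, 0.3, 4), rng.lognormal(4, 0.3, 4), n_extra=30, rng=rng)
        a, b = ["A0", "A1", "A2", "A3"], ["B0", "B1", "B2", "B3"]
        d1 = differential_transcripts(qm, a, b, pseudocount=0.01)
        qm10 = QuantMatrix(qm.tpm * 10)
        d2 = differential_transcripts(qm10, a, b, pseudocount=0.1)
        assert list(d1["direction"]) == list(d2["direction"])
        np.testing.assert_allclose(d1["fc"], d2["fc"], rtol=1e-9)

    def test_null_simulation_type1_rate(self):
        """Welch t on 2000 null transcripts rejects at ~alpha (99% binomial band)."""
        rng = np.random.default_rng(11)
        n = 2000
        mat = rng.lognormal(3.0, 0.5, size=(n, 12))
        qm = QuantMatrix(pd.DataFrame(mat, index=[f"T{i}" for i in range(n)],
                                      columns=[f"S{i}" for i in range(12)]))
        de = differential_transcripts(qm, [f"S{i}" for i in range(6)],
                                      [f"S{i}" for i in range(6, 12)])
        rate = (de["p"] <= 0.05).mean()
        half = 2.576 * np.sqrt(0.05 * 0.95 / n)
        assert 0.05 - half <= rate <= 0.05 + half
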