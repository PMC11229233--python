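import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from oracles import chi2_textbook
from promevol.events import DScore
from promevol.expression import (
    bin_by_dP,
    classify_germ_soma,
    compute_rpkm,
    cross_species_de,
    estimate_size_factors,
    volcano_classify,
)
from promevol.ingest import InputError
from promevol.simulate import SimulationConfig, simulate_counts


def profile(**kw):
    base = {"gene_id": "g", "vasa_log2fc": np.nan, "vasa_padj": np.nan,
            "ovary_rpkm": np.nan, "embryo_rpkm": np.nan, "osc_rpkm": np.nan}
    base.update(kw)
    return base


class TestRPKM:
    def test_definition(self):
        assert compute_rpkm(100, 1000, 1_000_000) == 100.0

    def test_zero_reads(self):
        assert compute_rpkm(0, 1000, 1_000_000) == 0.0

    def test_length_proportionality(self):
        assert compute_rpkm(10, 2000, 1e6) == compute_rpkm(10, 1000, 1e6) / 2

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            compute_rpkm(10, 0, 1e6)


class TestGermSomaClassification:
    def test_germline_profile(self):
        df = classify_germ_soma(pd.DataFrame([
            profile(vasa_log2fc=3, vasa_padj=0.001, ovary_rpkm=15, embryo_rpkm=10)
        ]))
        assert df["label"].iloc[0] == "germline"

    def test_soma_profile(self):
        df = classify_germ_soma(pd.DataFrame([
            profile(vasa_log2fc=-2, vasa_padj=0.005, ovary_rpkm=12, osc_rpkm=30, embryo_rpkm=1)
        ]))
        assert df["label"].iloc[0] == "soma"

    @pytest.mark.parametrize("kw", [
        dict(vasa_log2fc=2, vasa_padj=0.001, ovary_rpkm=15, embryo_rpkm=10),  # strict > 2
        dict(vasa_log2fc=3, vasa_padj=0.01, ovary_rpkm=15, embryo_rpkm=10),   # strict < 0.01
        dict(vasa_log2fc=3, vasa_padj=0.001, ovary_rpkm=10, embryo_rpkm=10),  # strict > 10
        dict(vasa_log2fc=3, vasa_padj=0.001, ovary_rpkm=15, embryo_rpkm=9),   # strict > 9
        dict(vasa_log2fc=-1, vasa_padj=0.005, ovary_rpkm=12, osc_rpkm=30, embryo_rpkm=1),
        dict(vasa_log2fc=-2, vasa_padj=0.005, ovary_rpkm=12, osc_rpkm=20, embryo_rpkm=1),
        dict(vasa_log2fc=-2, vasa_padj=0.005, ovary_rpkm=12, osc_rpkm=30, embryo_rpkm=2),
    ])
    def test_boundaries_are_strict(self, kw):
        df = classify_germ_soma(pd.DataFrame([profile(**kw)]))
        assert df["label"].iloc[0] == "neither"

    def test_missing_data_reported(self):
        df = classify_germ_soma(pd.DataFrame([profile()]))
        assert df["label"].iloc[0] == "neither"
        assert df["reasons"].iloc[0] == "missing_data"

    @given(st.data())
    def test_labels_are_mutually_exclusive(self, data):
        row = profile(
            vasa_log2fc=data.draw(st.floats(-5, 5)),
            vasa_padj=data.draw(st.floats(0, 1)),
            ovary_rpkm=data.draw(st.floats(0, 50)),
            embryo_rpkm=data.draw(st.floats(0, 50)),
            osc_rpkm=data.draw(st.floats(0, 50)),
        )
        df = classify_germ_soma(pd.DataFrame([row]))
        assert df["label"].iloc[0] in {"germline", "soma", "neither"}


class TestCrossSpeciesDE:
    def small_data(self, seed=10, n=120, **kw):
        cfg = SimulationConfig(seed=seed, n_expression_genes=n, **kw)
        return simulate_counts(cfg)

    def test_null_case_equal_counts_equal_lengths(self):
        counts = pd.DataFrame(
            np.tile([[100, 120, 90, 110]], (20, 1)),
            index=[f"g{i}" for i in range(20)],
        )
        counts_b = counts.copy()
        counts_b.index = [f"{g}_b" for g in counts.index]
        lengths = {g: 1000.0 for g in counts.index}
        lengths_b = {g: 1000.0 for g in counts_b.index}
        de, _ = cross_species_de(
            counts, counts_b, dict(zip(counts.index, counts_b.index)), lengths, lengths_b
        )
        np.testing.assert_allclose(de["log2fc"], 0.0, atol=1e-8)

    def test_length_doubling_shifts_one_gene_by_one(self):
        data = self.small_data(seed=11, n=60, length_divergence_sdlog=0.0)
        de1, _ = cross_species_de(
            data["counts_a"], data["counts_b"], data["orthologs"],
            data["lengths_a"], data["lengths_b"],
        )
        target = de1["gene_id"].iloc[0]
        lb = dict(data["lengths_b"])
        lb[data["orthologs"][target]] *= 2.0
        de2, _ = cross_species_de(
            data["counts_a"], data["counts_b"], data["orthologs"], data["lengths_a"], lb
        )
        shift = de2.set_index("gene_id")["log2fc"] - de1.set_index("gene_id")["log2fc"]
        assert shift[target] == pytest.approx(1.0, abs=1e-6)
        others = shift.drop(target)
        np.testing.assert_allclose(others, 0.0, atol=1e-6)

    def test_global_length_scaling_offsets_all_lfc(self):
        data = self.small_data(seed=12, n=60)
        de1, _ = cross_species_de(
            data["counts_a"], data["counts_b"], data["orthologs"],
            data["lengths_a"], data["lengths_b"],
        )
        la = {k: 3.0 * v for k, v in data["lengths_a"].items()}
        de2, _ = cross_species_de(
            data["counts_a"], data["counts_b"], data["orthologs"], la, data["lengths_b"]
        )
        shift = de2["log2fc"] - de1["log2fc"]
        np.testing.assert_allclose(shift, -np.log2(3.0), atol=1e-6)

    def test_permuted_null_pvalues_uniform(self):
        data = self.small_data(seed=13, n=1000, de_fraction=0.0)
        de, _ = cross_species_de(
            data["counts_a"], data["counts_b"], data["orthologs"],
            data["lengths_a"], data["lengths_b"],
        )
        ks = sps.kstest(de["p"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_non_one_to_one_orthologs_dropped_and_logged(self):
        data = self.small_data(seed=14, n=30)
        orth = dict(data["orthologs"])
        genes = list(orth)
        orth[genes[0]] = orth[genes[1]]  # two A genes -> same B gene
        de, excl = cross_species_de(
            data["counts_a"], data["counts_b"], orth, data["lengths_a"], data["lengths_b"]
        )
        assert set(excl["reason"]) == {"not_one_to_one"}
        assert len(de) == 28

    def test_all_zero_gene_excluded(self):
        data = self.small_data(seed=15, n=30)
        ca = data["counts_a"].copy()
        cb = data["counts_b"].copy()
        g0 = ca.index[0]
        ca.loc[g0] = 0
        cb.loc[data["orthologs"][g0]] = 0
        de, excl = cross_species_de(
            ca, cb, data["orthologs"], data["lengths_a"], data["lengths_b"]
        )
        assert g0 not in set(de["gene_id"])
        assert ("all_zero" == excl.set_index("gene_id").loc[g0, "reason"])

    def test_too_few_samples_rejected(self):
        data = self.small_data(seed=16, n=10)
        with pytest.raises(InputError):
            cross_species_de(
                data["counts_a"].iloc[:, :1], data["counts_b"], data["orthologs"],
                data["lengths_a"], data["lengths_b"],
            )

    def test_size_factors_recover_library_scaling(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(5, 1, size=200)
        counts = pd.DataFrame(
            {f"s{j}": np.round(base * f) for j, f in enumerate([1.0, 2.0, 0.5, 1.0])}
        )
        sf = estimate_size_factors(counts)
        np.testing.assert_allclose(sf / sf.iloc[0], [1.0, 2.0, 0.5, 1.0], rtol=1e-6)

    def test_matches_pydeseq2_on_equal_lengths(self):
        pydeseq2 = pytest.importorskip("pydeseq2")
        import warnings

        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        data = self.small_data(seed=7, n=150, length_divergence_sdlog=0.0)
        la = {k: 1000.0 for k in data["lengths_a"]}
        lb = {k: 1000.0 for k in data["lengths_b"]}
        de, _ = cross_species_de(
            data["counts_a"], data["counts_b"], data["orthologs"], la, lb
        )
        counts = pd.concat(
            [data["counts_a"], data["counts_b"].set_axis(data["counts_a"].index)], axis=1
        ).T
        meta = pd.DataFrame({"condition": ["A"] * 4 + ["B"] * 4}, index=counts.index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(counts=counts.astype(int), metadata=meta,
                               design="~condition", quiet=True)
            dds.deseq2()
            st_ = DeseqStats(dds, contrast=["condition", "A", "B"], quiet=True)
            st_.summary()
        merged = de.set_index("gene_id").join(
            st_.results_df, how="inner", lsuffix="_mine", rsuffix="_ds2"
        )
        r = np.corrcoef(merged["log2fc"], merged["log2FoldChange"])[0, 1]
        assert r > 0.999
        mine = set(merged.index[merged["padj_mine"] < 0.01])
        ds2 = set(merged.index[merged["padj_ds2"] < 0.01])
        assert len(mine & ds2) / max(1, len(mine | ds2)) > 0.8


class TestVolcano:
    def de_frame(self, lfc, padj):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(lfc))],
                             "log2fc": lfc, "padj": padj})

    def test_direction_flags(self):
        out = volcano_classify(self.de_frame([0.6, -0.6, 0.6], [0.01, 0.01, 0.9]))
        assert list(out["volcano"]) == ["toward_a", "toward_b", "ns"]

    def test_fc_boundary_strict(self):
        out = volcano_classify(self.de_frame([0.5], [0.001]))
        assert out["volcano"].iloc[0] == "ns"

    def test_failing_p_is_ns_despite_large_fc(self):
        out = volcano_classify(self.de_frame([-3.0], [0.9]))
        assert out["volcano"].iloc[0] == "ns"


class TestBinByDP:
    def make_inputs(self, dps, lfcs, padjs, labels):
        genes = [f"g{i}" for i in range(len(dps))]
        dscores = [DScore(g, v, int(3.5 * v), 350, 0.0, "conservation_dP")
                   for g, v in zip(genes, dps)]
        de = pd.DataFrame({"gene_id": genes, "log2fc": lfcs, "padj": padjs})
        lab = pd.DataFrame({"gene_id": genes, "label": labels})
        return dscores, de, lab

    def test_single_bin_no_significance(self):
        n = 6
        dscores, de, lab = self.make_inputs(
            [60] * n, [0.0] * n, [1.0] * n, ["germline", "soma"] * 3
        )
        out = bin_by_dP(dscores, de, lab)
        populated = out[(out["bin"] == ">50-75")]
        assert (populated["germ_frac"] == 0).all() and (populated["soma_frac"] == 0).all()

    def test_chi2_against_oracle(self):
        germ = (["germline"] * 20, [1.0] * 10 + [0.0] * 10)
        soma = (["soma"] * 20, [1.0] * 1 + [0.0] * 19)
        labels = germ[0] + soma[0]
        lfcs = germ[1] + soma[1]
        padjs = [0.001] * 40
        dscores, de, lab = self.make_inputs([40] * 40, lfcs, padjs, labels)
        out = bin_by_dP(dscores, de, lab)
        row = out[(out["bin"] == ">25-50") & (out["direction"] == "toward_a")].iloc[0]
        assert row["chi2"] == pytest.approx(chi2_textbook([[10, 10], [1, 19]]))

    def test_boundary_dp_25_excluded(self):
        dscores, de, lab = self.make_inputs([25.0], [2.0], [0.001], ["germline"])
        out = bin_by_dP(dscores, de, lab)
        assert out["germ_n"].sum() == 0
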