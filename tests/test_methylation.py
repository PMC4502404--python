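"""Methylation: normalisation, DM testing, DMR calling and annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from crossreg.errors import ValidationError
from crossreg.methylation import (
    DMR,
    adjust_type2,
    associate_gene,
    call_dmrs,
    classify_dmr_position,
    dm_test,
    effect_filter,
    quantile_normalize,
)


class TestQuantileNormalize:
    def test_identical_samples_unchanged(self):
        b = pd.DataFrame({"a": [0.1, 0.5, 0.9], "b": [0.1, 0.5, 0.9]})
        assert np.allclose(quantile_normalize(b), b)

    def test_hand_example(self):
        b = pd.DataFrame({"a": [0.1, 0.2, 0.3], "b": [0.3, 0.4, 0.5]})
        out = quantile_normalize(b)
        assert np.allclose(out["a"], [0.2, 0.3, 0.4])
        assert np.allclose(out["b"], [0.2, 0.3, 0.4])

    def test_sorted_vectors_identical_after(self, rng):
        b = pd.DataFrame(rng.uniform(size=(50, 4)))
        out = quantile_normalize(b)
        ref = np.sort(out.iloc[:, 0])
        for j in range(1, 4):
            assert np.allclose(np.sort(out.iloc[:, j]), ref)

    def test_preserves_range_and_size(self, rng):
        b = pd.DataFrame(rng.uniform(size=(100, 5)))
        out = quantile_normalize(b)
        assert out.shape == b.shape
        assert float(out.min().min()) >= 0 and float(out.max().max()) <= 1

    def test_single_sample_warns(self):
        b = pd.DataFrame({"a": [0.1, 0.2]})
        with pytest.warns(UserWarning):
            out = quantile_normalize(b)
        assert out.equals(b)


class TestAdjustType2:
    def design(self, b, n_type1):
        return pd.Series(
            ["I"] * n_type1 + ["II"] * (len(b) - n_type1), index=b.index
        )

    def test_only_type1_identity(self, rng):
        b = pd.DataFrame(rng.uniform(size=(20, 3)))
        out = adjust_type2(b, self.design(b, 20))
        assert out.equals(b)

    def test_ks_distance_not_increased(self, rng):
        # type II values systematically compressed toward 0.5
        t1 = rng.uniform(size=(200, 2))
        t2 = 0.5 + (rng.uniform(size=(200, 2)) - 0.5) * 0.6
        b = pd.DataFrame(np.vstack([t1, t2]))
        design = self.design(b, 200)
        out = adjust_type2(b, design)
        for j in range(2):
            before = stats.ks_2samp(t1[:, j], t2[:, j]).statistic
            after = stats.ks_2samp(
                out.iloc[:200, j], out.iloc[200:, j]
            ).statistic
            assert after <= before + 1e-9

    def test_monotone_within_sample(self, rng):
        b = pd.DataFrame(rng.uniform(size=(100, 1)))
        out = adjust_type2(b, self.design(b, 40))
        t2_before = b.iloc[40:, 0].to_numpy()
        t2_after = out.iloc[40:, 0].to_numpy()
        order = np.argsort(t2_before)
        assert (np.diff(t2_after[order]) >= -1e-12).all()

    def test_missing_design_rejected(self, rng):
        b = pd.DataFrame(rng.uniform(size=(10, 1)))
        with pytest.raises(ValidationError):
            adjust_type2(b, pd.Series(["I"] * 5, index=b.index[:5]))


class TestDmTest:
    def toy(self, values):
        cols = [f"c{i}" for i in range(7)] + [f"h{i}" for i in range(7)]
        m = pd.DataFrame(values, columns=cols)
        sp = pd.Series(["chimp"] * 7 + ["human"] * 7, index=cols)
        return m, sp

    def test_flat_probe_not_dm(self, rng):
        vals = np.tile(rng.uniform(0.2, 0.8, 10)[:, None], 14)
        m, sp = self.toy(vals)
        res = dm_test(m, sp)
        assert np.allclose(res["delta_beta"], 0)
        assert not res["dm_flag"].any()

    def test_unmoderated_matches_classical_t(self, rng):
        vals = rng.uniform(0.2, 0.8, (30, 14))
        m, sp = self.toy(vals)
        res = dm_test(m, sp, prior_df=0)
        for g in range(5):
            _, p = stats.ttest_ind(vals[g, :7], vals[g, 7:], equal_var=True)
            assert res["p"].iloc[g] == pytest.approx(p, rel=1e-10)

    def test_delta_beta_sign_is_chimp_minus_human(self, rng):
        vals = np.full((1, 14), 0.3) + rng.normal(0, 0.01, (1, 14))
        vals[0, :7] += 0.4
        m, sp = self.toy(vals)
        res = dm_test(m, sp)
        assert res["delta_beta"].iloc[0] > 0.3


class TestEffectFilter:
    def frame(self, deltas, flags=None):
        flags = flags if flags is not None else [True] * len(deltas)
        return pd.DataFrame(
            {"delta_beta": deltas, "dm_flag": flags,
             "direction": np.sign(deltas)},
            index=[f"p{i}" for i in range(len(deltas))],
        )

    def test_boundary_included(self):
        out = effect_filter(self.frame([0.1, -0.1]))
        assert len(out) == 2

    def test_below_boundary_removed(self):
        out = effect_filter(self.frame([0.099, 0.3]))
        assert list(out.index) == ["p1"]

    def test_zero_threshold_keeps_flagged(self):
        out = effect_filter(self.frame([0.01, 0.5], [True, False]), min_delta=0)
        assert list(out.index) == ["p0"]


def probes_frame(rows):
    """rows: (probe_id, chrom, pos, delta)"""
    return pd.DataFrame(
        {
            "chrom": [r[1] for r in rows],
            "pos": [r[2] for r in rows],
            "delta_beta": [r[3] for r in rows],
        },
        index=[r[0] for r in rows],
    )


def brute_force_dmrs(rows, max_gap=1000, min_probes=2):
    """Independent grouping oracle: probes are linked when consecutive on
    the same chromosome, closer than max_gap and same-signed; regions are
    the connected components of that link graph."""
    regions = []
    component = []
    for row in rows:
        if component:
            prev = component[-1]
            linked = (
                row[1] == prev[1]
                and row[2] - prev[2] < max_gap
                and np.sign(row[3]) == np.sign(prev[3])
            )
            if not linked:
                if len(component) >= min_probes:
                    regions.append(component)
                component = []
        component.append(row)
    if len(component) >= min_probes:
        regions.append(component)
    return [
        (c[0][1], c[0][2], c[-1][2], tuple(r[0] for r in c)) for c in regions
    ]


class TestCallDmrs:
    def test_worked_example(self):
        rows = [("a", "chr1", 100, 0.2), ("b", "chr1", 900, 0.2),
                ("c", "chr1", 1850, 0.2), ("d", "chr1", 3200, 0.2)]
        dmrs = call_dmrs(probes_frame(rows))
        assert len(dmrs) == 1
        d = dmrs[0]
        assert (d.start, d.end, d.probe_ids) == (100, 1850, ["a", "b", "c"])
        assert d.mean_delta_beta == pytest.approx(0.2)

    def test_direction_flip_blocks_region(self):
        rows = [("a", "chr1", 100, 0.2), ("b", "chr1", 600, -0.2)]
        assert call_dmrs(probes_frame(rows)) == []

    def test_gap_exactly_1kb_breaks(self):
        rows = [("a", "chr1", 100, 0.2), ("b", "chr1", 1100, 0.2)]
        assert call_dmrs(probes_frame(rows)) == []
        rows = [("a", "chr1", 100, 0.2), ("b", "chr1", 1099, 0.2)]
        assert len(call_dmrs(probes_frame(rows))) == 1

    def test_chromosome_break(self):
        rows = [("a", "chr1", 100, 0.2), ("b", "chr2", 200, 0.2)]
        assert call_dmrs(probes_frame(rows)) == []

    def test_unsorted_rejected(self):
        rows = [("a", "chr1", 900, 0.2), ("b", "chr1", 100, 0.2)]
        with pytest.raises(ValidationError):
            call_dmrs(probes_frame(rows))

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 5000),
                st.sampled_from([0.15, -0.15]),
                st.sampled_from(["chr1", "chr2"]),
            ),
            min_size=0,
            max_size=12,
        )
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force(self, raw):
        rows = sorted(
            (f"p{i}", chrom, pos, delta)
            for i, (pos, delta, chrom) in enumerate(raw)
        )
        rows = sorted(rows, key=lambda r: (r[1], r[2]))
        # unique positions per chromosome keep the grouping well-defined
        seen = set()
        rows = [r for r in rows if not ((r[1], r[2]) in seen or seen.add((r[1], r[2])))]
        expected = brute_force_dmrs(rows)
        got = [
            (d.chrom, d.start, d.end, tuple(d.probe_ids))
            for d in call_dmrs(probes_frame(rows))
        ]
        assert got == expected

    def test_each_probe_in_at_most_one_dmr(self, rng):
        pos = np.sort(rng.choice(20000, 50, replace=False))
        rows = [(f"p{i}", "chr1", int(p), float(rng.choice([0.2, -0.2])))
                for i, p in enumerate(pos)]
        dmrs = call_dmrs(probes_frame(rows))
        members = [p for d in dmrs for p in d.probe_ids]
        assert len(members) == len(set(members))


ANNOT = pd.DataFrame(
    {
        "probe_id": ["a", "b", "c", "d", "e"],
        "gene_id": ["G", "G", "H", None, "G"],
        "feature": ["TSS200", "TSS1500", "Body", None, "Body"],
    }
).dropna(subset=["probe_id"])


def dmr(probe_ids):
    return DMR(chrom="chr1", start=1, end=2, probe_ids=probe_ids,
               direction=1, mean_delta_beta=0.2)


class TestAssociateGene:
    def test_single_gene_kept(self):
        d = associate_gene(dmr(["a", "b"]), ANNOT)
        assert d is not None and d.gene_id == "G"

    def test_multiple_genes_discarded(self):
        assert associate_gene(dmr(["a", "c"]), ANNOT) is None

    def test_no_gene_discarded(self):
        assert associate_gene(dmr(["zz"]), ANNOT) is None


class TestClassifyPosition:
    def classify(self, probe_ids, gene="G"):
        d = dmr(probe_ids)
        d.gene_id = gene
        return classify_dmr_position(d, ANNOT)

    def test_promoter(self):
        assert self.classify(["a", "b"]) == "promoter"

    def test_genic(self):
        assert self.classify(["c"], gene="H") == "genic"

    def test_mixed(self):
        assert self.classify(["a", "e"]) == "mixed"

    def test_missing_annotation_is_mixed_with_warning(self):
        with pytest.warns(UserWarning):
            assert self.classify(["a", "zz"]) == "mixed"
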