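"""Folding engines, windowed MFE deltas and the structure filters."""

import numpy as np
import pandas as pd
import pytest

from hybridm6a import reference, structure
from hybridm6a.structure import (
    ENGINE_BUNDLED,
    StructureParams,
    delta_mfe,
    fold_mfe,
    position_structure_binning,
    positional_bin,
    structure_filter,
)


def random_seq(rng, n):
    return "".join("ACGU"[b] for b in rng.integers(0, 4, n))


class TestFoldBundled:
    def test_poly_a_has_no_structure(self):
        r = fold_mfe("A" * 12, ENGINE_BUNDLED)
        assert r.mfe == 0.0 and r.structure == "." * 12

    def test_gc_hairpin_exact_energy_and_structure(self):
        r = fold_mfe("GGGGAAAACCCC", ENGINE_BUNDLED)
        assert r.mfe == -12.0
        assert r.structure == "((((....))))"

    def test_gc_hairpin_at_least_as_stable_as_au_hairpin(self):
        gc = fold_mfe("GGGGAAAACCCC", ENGINE_BUNDLED).mfe
        au = fold_mfe("AAAAGGGGUUUU", ENGINE_BUNDLED).mfe
        assert gc <= au

    def test_short_sequence_is_unfoldable_by_convention(self):
        r = fold_mfe("GGGGCCCC", ENGINE_BUNDLED)
        assert r.mfe == 0.0

    def test_lone_pair_is_forbidden(self):
        # single GC pair with a big loop would be the only candidate
        r = fold_mfe("GAAAAAAAAAAC", ENGINE_BUNDLED)
        assert r.mfe == 0.0

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(60):
            seq = random_seq(rng, int(rng.integers(10, 19)))
            dp = fold_mfe(seq, ENGINE_BUNDLED).mfe
            assert dp == reference.brute_force_mfe(seq), seq

    def test_dot_bracket_energy_equals_reported_mfe(self, rng):
        for _ in range(30):
            seq = random_seq(rng, 40)
            r = fold_mfe(seq, ENGINE_BUNDLED)
            e = sum(structure.PAIR_ENERGY[seq[i] + seq[j]] for i, j in r.pairs())
            assert e == r.mfe


@pytest.mark.skipif(structure._vienna is None,
                    reason="ViennaRNA bindings unavailable")
class TestFoldExternal:
    def test_external_engine_is_deterministic(self):
        seq = "GGGAAAUCCCGGGAAAUCCC" * 3
        r1 = fold_mfe(seq, structure.ENGINE_EXTERNAL)
        r2 = fold_mfe(seq, structure.ENGINE_EXTERNAL)
        assert r1.mfe == r2.mfe and r1.structure == r2.structure

    def test_poly_a_is_unstructured(self):
        assert fold_mfe("A" * 30, structure.ENGINE_EXTERNAL).mfe == 0.0


def make_open_stem_pair(rng, window=61, stem=15):
    """Allele pair: B carries a planted hairpin, A is open at those positions."""
    seq = list(random_seq(rng, window))
    arm = slice(10, 10 + stem)
    comp = {"A": "U", "C": "G", "G": "C", "U": "A"}
    stem_start = 10 + stem + 6
    b = list(seq)
    for k in range(stem):
        b[stem_start + k] = comp[seq[arm][stem - 1 - k]]
    a = list(seq)
    for k in range(stem):
        a[stem_start + k] = "AC"[int(rng.integers(2))]
    return "".join(a), "".join(b)


class TestDeltaMfe:
    def test_identical_windows_have_zero_delta(self, rng):
        seq = random_seq(rng, 200)
        res = delta_mfe(seq, seq, 100)
        assert res is not None and res[2] == 0.0

    @pytest.mark.parametrize("engine", [ENGINE_BUNDLED, "auto"])
    def test_planted_stem_in_b_gives_positive_delta(self, engine, rng):
        params = StructureParams(engine=engine)
        for _ in range(10):
            a, b = make_open_stem_pair(rng)
            res = delta_mfe(a, b, 30, None, params)
            assert res is not None and res[2] > 0

    @pytest.mark.parametrize("window", [41, 61, 81])
    def test_sign_robust_to_window_size(self, window, rng):
        params = StructureParams(window=window, engine=ENGINE_BUNDLED)
        for _ in range(5):
            a, b = make_open_stem_pair(rng)
            # embed in a longer gene so every window fits
            pad = random_seq(rng, 50)
            res = delta_mfe(pad + a + pad, pad + b + pad, 80, None, params)
            assert res[2] > 0


class TestStructureFilter:
    @staticmethod
    def _table():
        return pd.DataFrame({
            "mfe_a": [-12.0, -5.0, -12.0],
            "mfe_b": [-2.0, -5.0, -3.0],
            "motif_disrupted": [False, False, True],
        })

    def test_filters_follow_the_rules(self):
        out = structure_filter(self._table(), StructureParams())
        # row 0 kept; row 1 fails the solid-structure threshold; row 2 is
        # excluded by its disrupting mutation
        assert list(out.index) == [0]

    def test_threshold_is_strict(self):
        df = pd.DataFrame({
            "mfe_a": [-8.0], "mfe_b": [-1.0], "motif_disrupted": [False]})
        assert len(structure_filter(df, StructureParams())) == 0


class TestPositionStructureBinning:
    def test_positional_bins_partition_the_gene(self):
        utr5, cds_end, length = 100, 800, 1000
        bins = [positional_bin(p, utr5, cds_end, length) for p in range(length)]
        counts = pd.Series(bins).value_counts()
        assert counts["5' UTR"] == 100
        assert counts["3' UTR"] == 200
        assert counts["CDS adjacent to 5' UTR"] == 70
        assert counts["CDS adjacent to 3' UTR"] == 70

    def test_quartiles_split_evenly_and_uniform_null_is_flat(self, rng):
        n = 400
        df = pd.DataFrame({
            "position_bin": rng.choice(structure.POSITION_BINS, n),
            "mfe": rng.normal(-8, 3, n),
            "methylated": rng.random(n) < 0.5,
        })
        table = position_structure_binning(df)
        q = pd.qcut(df["mfe"], 4, labels=["Q1", "Q2", "Q3", "Q4"])
        sizes = q.value_counts()
        assert sizes.max() - sizes.min() <= 1
        # methylation independent of both axes: cells within binomial CI
        grand = 100 * df["methylated"].mean()
        counts = df.groupby(["position_bin", pd.qcut(
            df["mfe"], 4, labels=["Q1", "Q2", "Q3", "Q4"])], observed=False).size()
        for pos_bin in table.index:
            for quart in table.columns:
                cell = table.loc[pos_bin, quart]
                n_cell = counts.loc[(pos_bin, quart)]
                if n_cell >= 5 and not np.isnan(cell):
                    margin = 300 * np.sqrt(0.25 / n_cell)  # 3 sigma in pct
                    assert abs(cell - grand) < margin

    def test_structure_dependent_methylation_gives_monotone_columns(self, rng):
        n = 2000
        mfe = rng.uniform(-20, 0, n)
        p = (mfe + 20) / 20 * 0.8  # less structured -> more methylated
        df = pd.DataFrame({
            "position_bin": rng.choice(structure.POSITION_BINS, n),
            "mfe": mfe,
            "methylated": rng.random(n) < p,
        })
        table = position_structure_binning(df)
        col_means = table.mean(axis=0)
        assert col_means["Q1"] < col_means["Q2"] < col_means["Q3"] < col_means["Q4"]
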