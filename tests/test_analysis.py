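"""Downstream analytics: replicate stats, class fractions, fold change,
copy-number views, operon groups, wobble decoding and codon correlation."""

import numpy as np
import pytest

from conftest import build_toy_catalog
from spotarray import probes
from spotarray.analysis import (
    SENSE_CODONS,
    CorrelationResult,
    DecodingRules,
    class_fractions,
    codon_usage_correlation,
    copy_group_medians,
    correlate,
    effective_codon_frequency,
    fold_change,
    group_mean_per_copy,
    per_copy_levels,
    read_codon_usage_tsv,
    replicate_stats,
)
from spotarray.datasets import synthetic_codon_usage
from spotarray.quantify import TrnaProfile


def _profile(levels):
    total = sum(levels.values())
    return TrnaProfile(level={k: 100 * v / total for k, v in levels.items()})


class TestReplicateStats:
    def test_identical_arrays_have_zero_spread(self):
        p = _profile({"a": 2.0, "b": 3.0, "c": 5.0})
        stats = replicate_stats([p, p, p])
        assert (stats.table["sd"] == 0).all()
        assert (stats.table["cv_percent"] == 0).all()

    def test_two_point_formulas(self):
        p1 = _profile({"a": 2.0, "b": 98.0})
        p2 = _profile({"a": 4.0, "b": 96.0})
        stats = replicate_stats([p1, p2])
        assert stats.table.loc["a", "median"] == pytest.approx(3.0)
        assert stats.table.loc["a", "sd"] == pytest.approx(np.sqrt(2), abs=1e-9)
        assert stats.table.loc["a", "cv_percent"] == pytest.approx(47.14, abs=0.01)

    def test_uniform_arrays_panel_median(self):
        n = 4
        p = _profile({f"p{i}": 1.0 for i in range(n)})
        stats = replicate_stats([p, p, p])
        assert stats.panel_median_level == pytest.approx(100 / n)

    def test_mismatched_panels_are_an_error(self):
        with pytest.raises(ValueError, match="panel"):
            replicate_stats([_profile({"a": 1.0}), _profile({"b": 1.0})])

    def test_single_profile_is_an_error(self):
        with pytest.raises(ValueError, match="two"):
            replicate_stats([_profile({"a": 1.0})])


def _two_class_toy():
    rng = np.random.default_rng(21)
    b1 = "".join(rng.choice(list("ACGT"), size=73))
    b2 = "".join(rng.choice(list("ACGT"), size=87))
    catalog = build_toy_catalog([("Ala", "GGC", b1), ("Leu", "CAG", b2)])
    return catalog, probes.design(catalog)


class TestClassFractions:
    def test_all_class_one(self):
        rng = np.random.default_rng(22)
        bodies = ["".join(rng.choice(list("ACGT"), size=73)) for _ in range(2)]
        catalog = build_toy_catalog([
            ("Ala", "GGC", bodies[0]), ("Gly", "GCC", bodies[1])
        ])
        ps = probes.design(catalog)
        profile = _profile({p.probe_id: 1.0 for p in ps.probes})
        fractions = class_fractions(profile, catalog, ps)
        assert fractions == {"I": pytest.approx(100.0), "II": 0.0}

    def test_constructed_60_40_split(self):
        catalog, ps = _two_class_toy()
        by_class = {
            p.probe_id: catalog.species_by_id()[p.targets[0]].size_class
            for p in ps.probes
        }
        levels = {
            pid: (60.0 if cls == "I" else 40.0) for pid, cls in by_class.items()
        }
        fractions = class_fractions(_profile(levels), catalog, ps)
        assert fractions["I"] == pytest.approx(60.0)
        assert fractions["II"] == pytest.approx(40.0)

    def test_fractions_are_complementary(self, panel, ecoli_like_catalog):
        rng = np.random.default_rng(23)
        levels = {p.probe_id: float(v) for p, v in
                  zip(panel.probes, rng.random(len(panel.probes)) + 0.1)}
        fractions = class_fractions(_profile(levels), ecoli_like_catalog, panel)
        assert fractions["I"] + fractions["II"] == pytest.approx(100.0)

    def test_mixed_class_probe_is_an_error(self):
        rng = np.random.default_rng(24)
        body = "".join(rng.choice(list("ACGT"), size=73))
        variant = body[:-1] + ("A" if body[-1] != "A" else "G")
        with pytest.warns(UserWarning):
            catalog = build_toy_catalog([
                ("Ala", "GGC", body), ("Leu", "CAG", variant)
            ])
        ps = probes.design(catalog)
        assert len(ps.probes) == 1  # near-identical pair shares a probe
        profile = _profile({ps.probes[0].probe_id: 1.0})
        with pytest.raises(ValueError, match="both size classes"):
            class_fractions(profile, catalog, ps)


class TestFoldChange:
    def test_identity(self):
        p = _profile({"a": 2.0, "b": 3.0})
        assert fold_change(p, p) == {"a": 1.0, "b": 1.0}

    def test_three_fold(self):
        p = _profile({"a": 9.0, "b": 91.0})
        c = _profile({"a": 3.0, "b": 97.0})
        assert fold_change(p, c)["a"] == pytest.approx(3.0)

    def test_overexpression_level_implies_control(self):
        # an 8.4-fold rise to 11.6% implies a 1.38% control level
        control_a = 11.6 / 8.4
        p = _profile({"a": 11.6, "b": 100 - 11.6})
        c = _profile({"a": control_a, "b": 100 - control_a})
        assert fold_change(p, c)["a"] == pytest.approx(8.4, rel=1e-9)
        assert control_a == pytest.approx(1.38, abs=0.01)

    def test_zero_control_is_undefined_not_infinite(self):
        p = _profile({"a": 10.0, "b": 90.0})
        c = TrnaProfile(level={"a": 0.0, "b": 100.0})
        ratios = fold_change(p, c)
        assert np.isnan(ratios["a"])
        assert np.isfinite(ratios["b"])


class TestCopyNumberViews:
    def test_copy_group_medians_toy(self, panel, ecoli_like_catalog):
        profile = _profile({p.probe_id: 1.0 for p in panel.probes})
        medians = copy_group_medians(profile, ecoli_like_catalog, panel)
        assert all(k >= 1 for k in medians)
        for v in medians.values():
            assert v == pytest.approx(100 / 42)

    def test_copy_group_median_values(self):
        rng = np.random.default_rng(25)
        bodies = ["".join(rng.choice(list("ACGT"), size=73)) for _ in range(3)]
        from conftest import make_gene
        from spotarray.catalog import _build_catalog

        genes = [
            make_gene("Ala", "GGC", bodies[0], "g1"),
            make_gene("Gly", "GCC", bodies[1], "g2"),
            make_gene("Val", "TAC", bodies[2], "g3"),
            make_gene("Val", "TAC", bodies[2], "g4"),
        ]
        catalog = _build_catalog(genes)
        ps = probes.design(catalog)
        by_species = {p.targets[0]: p.probe_id for p in ps.probes}
        levels = {
            by_species["Ala-GGC-1"]: 1.0,
            by_species["Gly-GCC-1"]: 3.0,
            by_species["Val-TAC-1"]: 5.0,
        }
        medians = copy_group_medians(_profile(levels), catalog, ps)
        # percent levels: {1-copy: [11.11, 33.33], 2-copy: [55.56]}
        assert medians[1] == pytest.approx(100 * 2 / 9)
        assert medians[2] == pytest.approx(100 * 5 / 9)

    def test_per_copy_levels_divide_by_copies(
        self, panel, ecoli_like_catalog
    ):
        profile = _profile({p.probe_id: 1.0 for p in panel.probes})
        frame = per_copy_levels(profile, ecoli_like_catalog, panel)
        for _, row in frame.iterrows():
            assert row["level_per_copy"] == pytest.approx(
                row["level_percent"] / row["gene_copies"]
            )

    def test_per_copy_levels_ordered_along_chromosome(
        self, panel, ecoli_like_catalog
    ):
        profile = _profile({p.probe_id: 1.0 for p in panel.probes})
        frame = per_copy_levels(profile, ecoli_like_catalog, panel)
        mids = frame["locus_midpoint"].dropna().to_numpy()
        assert (np.diff(mids) >= 0).all()

    def test_group_mean_per_copy_toy_groups(self, panel, ecoli_like_catalog):
        frame = group_mean_per_copy(
            _profile({p.probe_id: 1.0 for p in panel.probes}),
            ecoli_like_catalog, panel,
        )
        assert "other" in set(frame["group"])
        assert (frame.loc[frame["n"] == 1, "sd_per_copy"] == 0).all()
        operon_groups = [g for g in frame["group"] if g.startswith("rrn_")]
        assert len(operon_groups) == 5

    def test_group_means_match_hand_values(self):
        # toy groups {[1,1,1], [1,2,3]} -> means {1.0, 2.0}
        vals_a, vals_b = [1.0, 1.0, 1.0], [1.0, 2.0, 3.0]
        assert np.mean(vals_a) == 1.0 and np.mean(vals_b) == 2.0
        assert np.std(vals_a, ddof=1) == 0.0


class TestWobbleDecoding:
    def test_gu_wobble_reads_two_codons(self):
        rules = DecodingRules()
        assert rules.decoded_codons("GGC") == ("GCC", "GCT")

    def test_sole_decoder_collects_full_usage(self):
        rng = np.random.default_rng(26)
        body = "".join(rng.choice(list("ACGT"), size=73))
        catalog = build_toy_catalog([("Ala", "TGC", body)])
        usage = {c: 0.0 for c in SENSE_CODONS}
        usage["GCA"] = 0.6  # read by Watson-Crick at the wobble position
        usage["GCG"] = 0.4  # read by U:G wobble
        freq = effective_codon_frequency(usage, catalog)
        assert freq["Ala-TGC-1"] == pytest.approx(1.0)

    def test_species_decoding_only_stops_scores_zero(self):
        rng = np.random.default_rng(27)
        bodies = ["".join(rng.choice(list("ACGT"), size=73)) for _ in range(2)]
        catalog = build_toy_catalog([
            ("Leu", "TTA", bodies[0]),  # reads TAA/TAG, both stops
            ("Ala", "TGC", bodies[1]),
        ])
        usage = {c: 1 / len(SENSE_CODONS) for c in SENSE_CODONS}
        with pytest.warns(UserWarning, match="decoded by no species"):
            freq = effective_codon_frequency(usage, catalog)
        assert freq["Leu-TTA-1"] == 0.0

    def test_shared_codon_splits_equally(self):
        rng = np.random.default_rng(28)
        bodies = ["".join(rng.choice(list("ACGT"), size=73)) for _ in range(2)]
        catalog = build_toy_catalog([
            ("Ala", "TGC", bodies[0]),  # decodes GCA, GCG
            ("Ala", "CGC", bodies[1]),  # decodes GCG only
        ])
        usage = {c: 0.0 for c in SENSE_CODONS}
        usage["GCG"] = 0.5
        freq = effective_codon_frequency(usage, catalog)
        assert freq["Ala-TGC-1"] == pytest.approx(0.25)
        assert freq["Ala-CGC-1"] == pytest.approx(0.25)

    def test_equal_split_conserves_usage_mass(self, ecoli_like_catalog):
        usage = synthetic_codon_usage(seed=3)
        rules = DecodingRules()
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            freq = effective_codon_frequency(usage, ecoli_like_catalog, rules)
        decoded = set()
        for sp in ecoli_like_catalog.species:
            decoded |= set(rules.decoded_codons(sp.anticodon))
        decoded_mass = sum(usage[c] for c in decoded)
        assert sum(freq.values()) == pytest.approx(decoded_mass, abs=1e-12)

    def test_incomplete_usage_table_is_an_error(self, ecoli_like_catalog):
        with pytest.raises(ValueError, match="lacks sense codons"):
            effective_codon_frequency({"GCA": 1.0}, ecoli_like_catalog)


class TestCorrelate:
    def test_perfect_linear_relation(self):
        x = {"a": 1.0, "b": 2.0, "c": 3.0}
        y = {k: 2 * v for k, v in x.items()}
        assert correlate(x, y).r_squared == pytest.approx(1.0)

    def test_hand_computed_quarter(self):
        x = {"a": 1.0, "b": 2.0, "c": 3.0}
        y = {"a": 1.0, "b": 3.0, "c": 2.0}
        assert correlate(x, y).r_squared == pytest.approx(0.25, abs=1e-12)

    def test_constant_vector_is_an_error(self):
        x = {"a": 1.0, "b": 2.0, "c": 3.0}
        y = {"a": 5.0, "b": 5.0, "c": 5.0}
        with pytest.raises(ValueError, match="zero variance"):
            correlate(x, y)

    def test_affine_invariance(self):
        rng = np.random.default_rng(29)
        x = {f"k{i}": float(v) for i, v in enumerate(rng.random(10))}
        y = {f"k{i}": float(v) for i, v in enumerate(rng.random(10))}
        base = correlate(x, y).r_squared
        y2 = {k: 7.0 * v - 3.0 for k, v in y.items()}
        assert correlate(x, y2).r_squared == pytest.approx(base, rel=1e-9)

    def test_exclusion_list_applies(self):
        x = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 50.0}
        y = {"a": 1.0, "b": 2.0, "c": 3.0, "d": -50.0}
        assert correlate(x, y, exclude=("d",)).r_squared == pytest.approx(1.0)


class TestCodonUsageCorrelation:
    def test_truth_proportional_to_frequency_gives_r2_one(
        self, panel, ecoli_like_catalog
    ):
        import warnings

        usage = synthetic_codon_usage(seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            freq = effective_codon_frequency(usage, ecoli_like_catalog)
        probe_vals = {
            p.probe_id: sum(freq[s] for s in p.targets) for p in panel.probes
        }
        profile = _profile(probe_vals)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = codon_usage_correlation(
                profile, ecoli_like_catalog, panel, usage
            )
        assert isinstance(result, CorrelationResult)
        assert result.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_sec_probe_excluded_by_default(self, panel, ecoli_like_catalog):
        import warnings

        usage = synthetic_codon_usage(seed=5)
        profile = _profile({p.probe_id: 1.0 + i for i, p in
                            enumerate(panel.probes)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = codon_usage_correlation(
                profile, ecoli_like_catalog, panel, usage
            )
        assert any("SeC" in pid for pid in result.excluded)
        assert result.n == len(panel.probes) - len(result.excluded)


def test_codon_usage_tsv_reader(tmp_path):
    path = tmp_path / "usage.tsv"
    path.write_text("codon\tfreq\nGCU\t0.4\nGCA\t0.6\n")
    usage = read_codon_usage_tsv(path)
    assert usage == {"GCT": 0.4, "GCA": 0.6}
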