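import hashlib

import numpy as np
import pytest

import mdtraj as md

import immunoprofile as ip
from immunoprofile.io_formats import write_structure
from immunoprofile.synthetic_data import (
    SyntheticConfig,
    build_ideal_structure,
    null_config,
    recovery_config,
    simulate_cohort,
    simulate_proteins,
)

SMALL = dict(length_log_mean=5.2, length_max=400)


def dssp3(structure, tmp_path, name):
    path = tmp_path / f"{name}.pdb"
    write_structure(structure, path)
    codes = md.compute_dssp(md.load(str(path)), simplified=True)[0]
    return [{"H": "helix", "E": "sheet", "C": "coil"}[c] for c in codes]


class TestIdealStructures:
    def test_helix_plan_labelled_helix_by_reference(self, tmp_path):
        st = build_ideal_structure([("helix", 20)])
        ref = dssp3(st, tmp_path, "h")
        assert all(lab == "helix" for lab in ref[2:-2])

    def test_hairpin_plan_labelled_sheet_by_reference(self, tmp_path):
        st = build_ideal_structure([("strand", 6), ("coil", 4), ("strand", 6)])
        ref = dssp3(st, tmp_path, "hp")
        assert ref.count("sheet") >= 6

    def test_same_seed_gives_identical_coordinates(self):
        plan = [("coil", 10), ("helix", 8), ("coil", 6)]
        a = build_ideal_structure(plan, seed=5)
        b = build_ideal_structure(plan, seed=5)
        for ra, rb in zip(a.residues, b.residues):
            np.testing.assert_array_equal(ra.coords, rb.coords)

    def test_empty_plan_is_error(self):
        with pytest.raises(ValueError):
            build_ideal_structure([])


class TestSimulateProteins:
    def test_zero_tm_rate_gives_no_tm_ranges(self):
        cfg = SyntheticConfig(n_proteins=40, tm_protein_rate=0.0, **SMALL)
        proteins = simulate_proteins(cfg, 1)
        assert all(not p.annotations.tm_ranges for p in proteins)

    def test_tm_incidence_within_three_se(self):
        cfg = SyntheticConfig(n_proteins=500, **SMALL)
        proteins = simulate_proteins(cfg, 2)
        rate = np.mean([bool(p.annotations.tm_ranges) for p in proteins])
        se = np.sqrt(0.3 * 0.7 / 500)
        assert abs(rate - cfg.tm_protein_rate) <= 3 * se

    def test_deterministic_across_runs(self):
        cfg = SyntheticConfig(n_proteins=20, **SMALL)
        a = simulate_proteins(cfg, 3)
        b = simulate_proteins(cfg, 3)
        for pa, pb in zip(a, b):
            assert pa.sequence == pb.sequence
            assert pa.ss3 == pb.ss3
            np.testing.assert_array_equal(pa.disorder, pb.disorder)

    def test_invariants(self):
        cfg = SyntheticConfig(n_proteins=50, **SMALL)
        for p in simulate_proteins(cfg, 4):
            assert cfg.length_min <= len(p) <= cfg.length_max
            assert len(p.ss3) == len(p) == len(p.disorder)
            assert np.all((p.disorder >= 0) & (p.disorder <= 1))
            for i, j in p.annotations.disulfide_pairs:
                assert p.sequence[i - 1] == p.sequence[j - 1] == "C"
            for s, e in p.annotations.tm_ranges:
                assert 1 <= s <= e <= len(p)


class TestSimulateAntibodies:
    def test_null_model_hits_target_rate(self):
        cfg = null_config(n_proteins=1000, immunogens_per_protein=2, **SMALL)
        cohort = simulate_cohort(cfg, 5)
        rate = cohort.truth.latent_success.mean()
        se = np.sqrt(0.8 * 0.2 / len(cohort.records))
        assert abs(rate - 0.8) <= 3 * se

    def test_coverage_fractions_within_three_se(self):
        cfg = SyntheticConfig(n_proteins=1000, immunogens_per_protein=2, **SMALL)
        cohort = simulate_cohort(cfg, 6)
        n = len(cohort.records)
        for tech, target in (("wb", 0.413), ("ihc", 0.7443), ("icc", 0.5959)):
            tested = np.mean([getattr(r, f"outcome_{tech}") != "untested"
                              for r in cohort.records])
            se = np.sqrt(target * (1 - target) / n)
            assert abs(tested - target) <= 3 * se, tech

    def test_latent_probabilities_follow_logistic_model(self):
        cfg = SyntheticConfig(n_proteins=100, **SMALL)
        cohort = simulate_cohort(cfg, 7)
        eta = cfg.effect.linear_predictor(cohort.truth.features)
        np.testing.assert_allclose(cohort.truth.probabilities,
                                   1 / (1 + np.exp(-eta)), rtol=1e-12)

    def test_windows_lie_within_proteins(self):
        cfg = SyntheticConfig(n_proteins=100, immunogens_per_protein=3, **SMALL)
        cohort = simulate_cohort(cfg, 8)
        lengths = {p.protein_id: len(p) for p in cohort.proteins}
        for record, (_, row) in zip(cohort.records,
                                    cohort.truth.features.iterrows()):
            assert 1 <= row["start"] <= row["end"] <= lengths[record.protein_id]
            protein = cohort.protein(record.protein_id)
            assert record.immunogen_sequence == \
                protein.sequence[row["start"] - 1:row["end"]]


class TestPipelineConsistency:
    def test_structure_mode_reproduces_true_features(self):
        cfg = SyntheticConfig(n_proteins=12, immunogens_per_protein=4,
                              with_structures=True, length_log_mean=5.0,
                              length_max=300)
        cohort = simulate_cohort(cfg, 9)
        track = ip.cohort_table(cohort, use_structures=False)
        geom = ip.cohort_table(cohort, use_structures=True, n_points=120)
        for col in ("disorder_class", "position_class", "tm_class"):
            assert (track[col] == geom[col]).mean() >= 0.99, col
        assert (track["majority_ss"] == geom["majority_ss"]).mean() >= 0.90

    def test_profiled_features_match_ground_truth_in_track_mode(self):
        cfg = SyntheticConfig(n_proteins=200, **SMALL)
        cohort = simulate_cohort(cfg, 10)
        table = ip.cohort_table(cohort)
        truth = cohort.truth.features
        for col in ("position_class", "disorder_class", "majority_ss",
                    "tm_class", "has_disulfide", "has_ptm"):
            assert (table[col].to_numpy() == truth[col].to_numpy()).all(), col


class TestEndToEndDeterminism:
    @staticmethod
    def digest(seed):
        cfg = SyntheticConfig(n_proteins=40, immunogens_per_protein=2,
                              with_structures=True, length_log_mean=5.0,
                              length_max=300)
        cohort = simulate_cohort(cfg, seed)
        table = ip.cohort_table(cohort)
        kept, _ = ip.apply_filters(table)
        report = ip.success_rate_by_group(kept, "position_class")
        h = hashlib.sha256()
        h.update(table.to_csv(float_format="%.6f").encode())
        h.update(str(report.to_dict()).encode())
        for p in cohort.proteins[:3]:
            h.update(p.structure.sequence.encode())
            h.update(np.ascontiguousarray(p.structure.residues[0].coords).tobytes())
        return h.hexdigest()

    def test_identical_digests_for_identical_seeds(self):
        assert self.digest(11) == self.digest(11)

    def test_different_seeds_differ(self):
        assert self.digest(11) != self.digest(12)


class TestRecovery:
    def test_injected_disorder_odds_ratio_recovered(self):
        cfg = recovery_config(odds_ratio=2.0, n_records=2000)
        cohort = simulate_cohort(cfg, 13)
        kept, _ = ip.apply_filters(ip.cohort_table(cohort))
        estimate = ip.odds_ratio(kept, "disorder_class", "high", "low")
        assert 1.5 <= estimate <= 2.7
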