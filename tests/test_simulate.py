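"""Synthetic cohort generator: planted structure and determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from connstates import CohortSpec, generate_cohort, validate_connectome
from connstates.core import LabelingError, RegionLabeling
from connstates.simulate import (
    ARCHETYPES,
    default_archetypes,
    generate_behavior,
    generate_behavior_table,
    generate_labels,
    generate_structural_backbone,
    generate_subject_fc,
    generate_subject_sc,
    largest_remainder_counts,
    raw_task_fc,
)


@pytest.mark.parametrize(
    "n, fractions, expected",
    [
        (10, (0.5, 0.3, 0.2), [5, 3, 2]),
        (9, (1 / 3, 1 / 3, 1 / 3), [3, 3, 3]),
        (71, (0.3, 0.3, 0.4), [21, 21, 29]),
    ],
)
def test_largest_remainder_counts(n, fractions, expected):
    counts = largest_remainder_counts(n, fractions)
    assert counts == expected and sum(counts) == n


def test_generate_labels_counts_and_determinism():
    spec = CohortSpec(n_regions=50, label_fractions=(0.5, 0.3, 0.2), seed=7)
    lab1, lab2 = generate_labels(spec), generate_labels(spec)
    assert lab1.labels == lab2.labels
    assert lab1.class_counts() == {"P": 25, "N": 15, "O": 10}


def test_generate_labels_empty_class_errors():
    spec = CohortSpec(n_regions=9, label_fractions=(0.98, 0.01, 0.01), seed=0)
    with pytest.raises(LabelingError):
        generate_labels(spec)


class TestBackbone:
    def test_edge_prob_one_gives_complete_graph(self, rng):
        spec = CohortSpec(n_regions=9, backbone_edge_prob={c: 1.0 for c in "PP NN PN PO NO OO".split()})
        lab = RegionLabeling(list("PPPNNNOOO"))
        bb = generate_structural_backbone(lab, spec, rng)
        assert bb.n_edges == 9 * 8 // 2

    def test_zero_prob_class_absent(self, rng):
        probs = {c: 1.0 for c in "PP NN PN PO NO OO".split()}
        probs["OO"] = 0.0
        spec = CohortSpec(n_regions=9, backbone_edge_prob=probs)
        lab = RegionLabeling(list("PPPNNNOOO"))
        bb = generate_structural_backbone(lab, spec, rng)
        labels = lab.label_array()
        assert not np.any((labels[bb.rows] == "O") & (labels[bb.cols] == "O"))

    def test_degenerate_lognormal_gives_unit_weights(self, rng):
        spec = CohortSpec(
            n_regions=9,
            backbone_edge_prob={c: 1.0 for c in "PP NN PN PO NO OO".split()},
            weight_lognormal=(0.0, 0.0),
        )
        bb = generate_structural_backbone(RegionLabeling(list("PPPNNNOOO")), spec, rng)
        assert np.all(bb.weights == 1.0)

    def test_empty_focus_class_errors(self, rng):
        probs = {c: 0.0 for c in "PP NN PN PO NO OO".split()}
        probs["OO"] = 1.0
        spec = CohortSpec(n_regions=9, backbone_edge_prob=probs)
        with pytest.raises(ValueError, match="raise backbone_edge_prob"):
            generate_structural_backbone(RegionLabeling(list("PPPNNNOOO")), spec, rng)


class TestSubjectSC:
    def _setup(self, retention, spurious, seed=3):
        spec = CohortSpec(
            n_regions=20,
            backbone_retention_prob=retention,
            spurious_edge_prob=spurious,
            seed=seed,
        )
        lab = generate_labels(spec)
        bb = generate_structural_backbone(lab, spec)
        return spec, bb

    def test_full_retention_no_spurious_matches_backbone(self, rng):
        spec, bb = self._setup(1.0, 0.0)
        sc = generate_subject_sc(bb, spec, rng)
        assert np.array_equal(sc > 0, bb.support_matrix())

    def test_zero_retention_empty(self, rng):
        spec, bb = self._setup(0.0, 0.0)
        assert generate_subject_sc(bb, spec, rng).sum() == 0

    def test_retention_rate_within_binomial_bounds(self):
        # 20 subjects at retention 0.9: per-edge presence ~ Binomial(20, 0.9)
        spec, bb = self._setup(0.9, 0.0)
        rngs = [np.random.default_rng(s) for s in range(20)]
        presence = np.mean(
            [generate_subject_sc(bb, spec, r)[bb.rows, bb.cols] > 0 for r in rngs],
            axis=0,
        )
        mean_presence = presence.mean()
        sd = np.sqrt(0.9 * 0.1 / (20 * bb.n_edges))
        assert abs(mean_presence - 0.9) < 3 * sd


class TestSubjectFC:
    def test_zero_parameters_give_near_zero_matrix(self, rng):
        from connstates.simulate import ArchetypeSpec, _CLASS_ORDER

        zero = {c: 0.0 for c in _CLASS_ORDER}
        arch = ArchetypeSpec(
            "flat",
            fc_base={s: zero for s in ("rest", "attention", "memory")},
            fc_slope={s: zero for s in ("rest", "attention", "memory")},
            fc_noise_sd=1e-12,
        )
        lab = RegionLabeling(list("PPPNNNOOO"))
        sc = np.ones((9, 9)) - np.eye(9)
        fc = generate_subject_fc(sc, lab, arch, "rest", rng)
        assert np.abs(fc).max() < 1e-9

    def test_rest_class_means_ordered(self):
        # planted rest structure: mean FC(NN) > mean FC(PP) > mean FC(PN)
        rng = np.random.default_rng(5)
        spec = CohortSpec(n_regions=200, seed=5)
        lab = generate_labels(spec, rng)
        bb = generate_structural_backbone(lab, spec, rng)
        sc = generate_subject_sc(bb, spec, rng)
        fc = generate_subject_fc(sc, lab, default_archetypes()["primary"], "rest", rng)
        iu, ju = np.triu_indices(200, k=1)
        cls = lab.pair_class_indices(iu, ju)
        vals = fc[iu, ju]
        mean_pp, mean_nn, mean_pn = (vals[cls == k].mean() for k in (0, 1, 2))
        assert mean_nn > mean_pp > mean_pn

    def test_positive_slope_couples_fc_to_weight(self):
        # attention dFC has slope > 0 on PP: Spearman(w, dFC) > 0 over PP pairs
        rng = np.random.default_rng(8)
        spec = CohortSpec(n_regions=200, seed=8)
        lab = generate_labels(spec, rng)
        bb = generate_structural_backbone(lab, spec, rng)
        sc = generate_subject_sc(bb, spec, rng)
        dfc = generate_subject_fc(sc, lab, default_archetypes()["primary"], "attention", rng)
        iu, ju = np.triu_indices(200, k=1)
        cls = lab.pair_class_indices(iu, ju)
        pp = (cls == 0) & (sc[iu, ju] > 0)
        rho = stats.spearmanr(sc[iu, ju][pp], dfc[iu, ju][pp]).statistic
        assert rho > 0


class TestBehavior:
    def test_zero_sd_returns_group_means(self, rng):
        spec = dict(CohortSpec().behavior_spec)
        spec["sd"] = {"RT": 0.0, "CS": 0.0, "DP": 0.0}
        rec = generate_behavior("secondary_RM", spec, rng)
        assert rec["DP_A"] == 2.6 and rec["DP_M"] == 1.4
        assert rec["DP_A"] - rec["DP_M"] == pytest.approx(1.2)

    def test_primary_spec_symmetric_in_tasks(self):
        means = CohortSpec().behavior_spec["primary"]
        assert means["DP_A"] == means["DP_M"]
        assert means["CS_A"] == means["CS_M"]

    def test_unknown_group_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_behavior("tertiary", CohortSpec().behavior_spec, rng)


class TestCohort:
    def test_pure_mixture_all_primary(self):
        spec = CohortSpec(n_subjects=5, n_regions=30, archetype_mixture=(1.0, 0.0, 0.0), seed=1)
        cohort = generate_cohort(spec)
        assert set(cohort.ground_truth["archetype"]) == {"primary"}

    def test_default_cohort_size_is_71(self):
        assert CohortSpec().n_subjects == 71
        assert CohortSpec().archetype_mixture == (0.66, 0.23, 0.11)

    def test_determinism_identical_cohorts(self):
        spec = CohortSpec(n_subjects=3, n_regions=30, seed=9)
        c1, c2 = generate_cohort(spec), generate_cohort(spec)
        for s1, s2 in zip(c1.subjects, c2.subjects):
            assert np.array_equal(s1.sc, s2.sc)
            assert np.array_equal(s1.fc_memory, s2.fc_memory)
        pd.testing.assert_frame_equal(c1.behavior, c2.behavior)

    def test_every_generated_subject_validates_100_seeds(self):
        base = CohortSpec(n_regions=30, seed=0)
        lab = generate_labels(base)
        bb = generate_structural_backbone(lab, base)
        arch = default_archetypes()["primary"]
        for seed in range(100):
            r = np.random.default_rng(seed)
            sc = generate_subject_sc(bb, base, r)
            from connstates import SubjectConnectome

            subj = SubjectConnectome(
                f"s{seed}",
                sc,
                generate_subject_fc(sc, lab, arch, "rest", r),
                generate_subject_fc(sc, lab, arch, "attention", r),
                generate_subject_fc(sc, lab, arch, "memory", r),
            )
            assert validate_connectome(subj).ok

    def test_behavior_table_matches_mixture(self):
        beh, gt = generate_behavior_table(CohortSpec(n_subjects=500, seed=3))
        frac = (gt["archetype"] == "primary").mean()
        assert abs(frac - 0.66) < 0.07
        assert len(beh) == 500


def test_raw_task_fc_round_trip(small_cohort):
    from connstates import task_fc_deviation

    s = small_cohort.subjects[0]
    raw = raw_task_fc(s, "attention")
    np.testing.assert_allclose(task_fc_deviation(raw, s.fc_rest), s.fc_attention, atol=1e-12)
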