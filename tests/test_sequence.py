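"""Stride-sequence inputs and recurrent fall-risk classification."""

import numpy as np
import pandas as pd
import pytest

from msgait import sequence, strides, synthetic
from msgait.types import WalkingBout

from conftest import make_profile

FS = 31.25


def make_bouts(cohort, n_bouts=2, n_strides=12, seed0=0):
    bouts = []
    for i, prof in enumerate(cohort):
        for b in range(n_bouts):
            chest, thigh, _, _ = synthetic.synth_walking_segment(
                prof, n_strides, seed=seed0 + 10 * i + b
            )
            wb = WalkingBout(bout_id=b, subject_id=prof.subject_id, start_s=0.0,
                             end_s=chest.shape[1] / FS, fs=FS,
                             chest_view=chest, thigh_view=thigh)
            strides.detect_bout_events(wb)
            bouts.append(wb)
    return bouts


def cohort_frame(cohort):
    return pd.DataFrame(
        [{"subject_id": p.subject_id, "fall_label": p.fall_label, "ABC": p.surveys["ABC"]}
         for p in cohort]
    )


@pytest.fixture(scope="module")
def separable_setup():
    cohort = synthetic.generate_cohort(
        10, 0.5, effect_config={"ap_amplitude": 0.55, "stride_time_cv": 2.0}, seed=7
    )
    return cohort_frame(cohort), make_bouts(cohort, seed0=500)


class TestBuildStrideInputs:
    def test_bout_shorter_than_k_contributes_nothing(self, separable_setup):
        cdf, bouts = separable_setup
        b = bouts[0]
        short = WalkingBout(bout_id=8, subject_id=b.subject_id, start_s=0, end_s=b.end_s,
                            fs=FS, chest_view=b.chest_view, thigh_view=b.thigh_view)
        short.strides = b.strides[:3]
        assert sequence.build_stride_inputs([short], cdf, k=4) == []

    def test_k_one_gives_one_input_per_stride(self, separable_setup):
        cdf, bouts = separable_setup
        b = bouts[0]
        inputs = sequence.build_stride_inputs([b], cdf, k=1)
        assert len(inputs) == len(b.strides)

    def test_sliding_window_count(self, separable_setup):
        cdf, bouts = separable_setup
        b = bouts[0]
        b5 = WalkingBout(bout_id=9, subject_id=b.subject_id, start_s=0, end_s=b.end_s,
                         fs=FS, chest_view=b.chest_view, thigh_view=b.thigh_view)
        b5.strides = b.strides[:5]
        assert len(sequence.build_stride_inputs([b5], cdf, k=4)) == 2  # strides 1-4, 2-5
        assert len(sequence.build_stride_inputs([b5], cdf, k=4, mode="disjoint")) == 1

    def test_abc_rides_as_constant_channel(self, separable_setup):
        cdf, bouts = separable_setup
        inputs = sequence.build_stride_inputs(bouts[:1], cdf, k=2, include_abc=True)
        x = inputs[0].data
        assert x.shape[0] == 7
        assert np.ptp(x[6]) == 0.0
        assert x[6, 0] == pytest.approx(
            float(cdf.set_index("subject_id").loc[inputs[0].subject_id, "ABC"])
        )

    def test_input_length_spans_k_strides(self, separable_setup):
        cdf, bouts = separable_setup
        b = bouts[0]
        inputs = sequence.build_stride_inputs([b], cdf, k=4)
        s = b.strides
        expect = int(round(s[3].next_contact_s * FS)) - int(round(s[0].foot_contact_s * FS))
        assert inputs[0].data.shape[1] == expect


class TestSequenceModels:
    def test_architecture_specs_match_reference(self):
        l2 = sequence.ARCHITECTURES["LSTM2"]
        assert l2.layers == [("lstm", 290, False), ("dropout", 0.30),
                             ("lstm", 10, True), ("dropout", 0.40)]
        assert l2.epochs == 55
        l3 = sequence.ARCHITECTURES["LSTM3"]
        assert [u for kind, u, *_ in l3.layers if kind == "lstm"] == [85, 85, 235]
        assert l3.epochs == 125

    def _balanced_subset(self, inputs, n=40):
        pos = [x for x in inputs if x.label == 1][: n // 2]
        neg = [x for x in inputs if x.label == 0][: n // 2]
        return pos + neg

    def test_training_is_deterministic_under_seed(self, separable_setup):
        cdf, bouts = separable_setup
        inputs = self._balanced_subset(sequence.build_stride_inputs(bouts, cdf, k=2))
        arch = sequence.reduced_architecture(hidden=8, epochs=2)
        m1 = sequence.train_sequence_model(inputs, arch, seed=3)
        m2 = sequence.train_sequence_model(inputs, arch, seed=3)
        s1 = m1.decision_scores([x.data.T for x in inputs[:10]])
        s2 = m2.decision_scores([x.data.T for x in inputs[:10]])
        assert np.array_equal(s1, s2)

    def test_scores_live_in_unit_interval(self, separable_setup):
        cdf, bouts = separable_setup
        inputs = self._balanced_subset(sequence.build_stride_inputs(bouts, cdf, k=2), 30)
        arch = sequence.reduced_architecture(hidden=8, epochs=2)
        model = sequence.train_sequence_model(inputs, arch, seed=0)
        s = model.decision_scores([x.data.T for x in inputs])
        assert np.all((s >= 0) & (s <= 1))

    def test_reference_architecture_smoke(self, separable_setup):
        cdf, bouts = separable_setup
        inputs = self._balanced_subset(sequence.build_stride_inputs(bouts, cdf, k=2), 10)
        model = sequence.train_sequence_model(inputs, sequence.ARCHITECTURES["LSTM2"],
                                              seed=0, epochs=1)
        assert model.predict_proba([inputs[0].data.T]).shape == (1, 2)


class TestModifiedLoso:
    def test_partitions_are_disjoint_every_fold(self, separable_setup):
        cdf, bouts = separable_setup
        inputs = sequence.build_stride_inputs(bouts, cdf, k=4)
        arch = sequence.reduced_architecture(hidden=8, epochs=2)
        out = sequence.loso_sequence_classification(inputs, arch, seed=0)
        for f in out.per_fold:
            assert f["subject"] != f["validation_subject"]
        # every subject tested exactly once
        assert sorted(f["subject"] for f in out.per_fold) == sorted(
            {x.subject_id for x in inputs}
        )

    def test_separable_cohort_learned(self, separable_setup):
        cdf, bouts = separable_setup
        inputs = sequence.build_stride_inputs(bouts, cdf, k=4)
        arch = sequence.reduced_architecture(hidden=16, epochs=6)
        out = sequence.loso_sequence_classification(inputs, arch, seed=0)
        assert out.auc_per_input >= 0.7
        assert out.auc_subject_median >= 0.7

    def test_shuffled_labels_near_chance(self, separable_setup):
        cdf, bouts = separable_setup
        inputs = sequence.build_stride_inputs(bouts, cdf, k=4)
        rng = np.random.default_rng(0)
        subjects = sorted({x.subject_id for x in inputs})
        # permute labels at the subject level so LOSO stays meaningful
        labels = {s: int(l) for s, l in zip(subjects, rng.permutation(
            [int(cdf.set_index("subject_id").loc[s, "fall_label"] == "faller")
             for s in subjects]))}
        for x in inputs:
            x.label = labels[x.subject_id]
        try:
            arch = sequence.reduced_architecture(hidden=8, epochs=2)
            out = sequence.loso_sequence_classification(inputs, arch, seed=1)
            assert 0.2 <= out.auc_per_input <= 0.8
        finally:
            for x in inputs:  # restore for other tests in the module
                x.label = int(cdf.set_index("subject_id").loc[x.subject_id,
                                                              "fall_label"] == "faller")

    def test_grid_driver_reports_every_configuration(self, separable_setup):
        cdf, bouts = separable_setup
        arch = sequence.reduced_architecture(hidden=4, epochs=1)
        grid = sequence.run_sequence_grid(bouts[:6], cdf, ks=(2, 40), archs=[arch],
                                          seed=0, include_abc=(False,))
        assert len(grid) == 2
        assert grid.loc[grid.k_strides == 40, "n_inputs"].iloc[0] == 0
        assert np.isnan(grid.loc[grid.k_strides == 40, "auc_per_input"].iloc[0])
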