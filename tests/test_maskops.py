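import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from arborsplit.maskops import apply_and, apply_eor, separate, trace_separated
from arborsplit.metric import diadem_score
from arborsplit.stack import BinaryMask, ImageStack
from arborsplit.trace import TraceConfig, trace_stack

SHAPE = (4, 5, 6)

stacks = hnp.arrays(
    dtype=np.float64,
    shape=SHAPE,
    elements=st.floats(0, 255, allow_nan=False),
).map(ImageStack)
masks = hnp.arrays(dtype=np.bool_, shape=SHAPE).map(BinaryMask)


def make_stack(values):
    return ImageStack(np.asarray(values, dtype=float))


class TestAndEor:
    def test_all_true_mask_is_identity(self, rng):
        img = make_stack(rng.uniform(0, 100, SHAPE))
        out = apply_and(img, BinaryMask(np.ones(SHAPE, dtype=bool)))
        assert np.array_equal(out.voxels, img.voxels)

    def test_all_false_mask_annihilates(self, rng):
        img = make_stack(rng.uniform(0, 100, SHAPE))
        out = apply_and(img, BinaryMask(np.zeros(SHAPE, dtype=bool)))
        assert not out.voxels.any()

    def test_half_plane_mask(self, rng):
        img = make_stack(rng.uniform(1, 100, SHAPE))
        m = np.zeros(SHAPE, dtype=bool)
        m[:, :, :3] = True
        out = apply_and(img, BinaryMask(m))
        assert np.array_equal(out.voxels[:, :, :3], img.voxels[:, :, :3])
        assert not out.voxels[:, :, 3:].any()

    def test_eor_self_is_zero(self, rng):
        img = make_stack(rng.uniform(0, 100, SHAPE))
        assert not apply_eor(img, img).voxels.any()

    def test_eor_with_zero_keeps_image(self, rng):
        img = make_stack(rng.integers(1, 100, SHAPE))
        out = apply_eor(img, make_stack(np.zeros(SHAPE)))
        assert np.array_equal(out.voxels, img.voxels)

    def test_shape_mismatch_rejected(self):
        img = make_stack(np.zeros(SHAPE))
        with pytest.raises(ValueError, match="shape mismatch"):
            apply_and(img, BinaryMask(np.zeros((2, 2, 2), dtype=bool)))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(img=stacks, mask=masks)
    def test_conservation_identity(self, img, mask):
        # AND(I,M) + EOR(I, AND(I,M)) == I voxel-exact: the decomposition
        # loses no signal
        part = apply_and(img, mask)
        rest = apply_eor(img, part)
        assert np.array_equal(part.voxels + rest.voxels, img.voxels)


class TestSeparate:
    def test_single_all_true_mask(self, rng):
        img = make_stack(rng.uniform(1, 100, SHAPE))
        parts = separate(img, [BinaryMask(np.ones(SHAPE, dtype=bool))])
        assert len(parts) == 2
        assert np.array_equal(parts[0].voxels, img.voxels)
        assert not parts[1].voxels.any()

    def test_two_half_masks_partition(self, rng):
        img = make_stack(rng.uniform(1, 100, SHAPE))
        m1 = np.zeros(SHAPE, dtype=bool)
        m1[:, :, :3] = True
        parts = separate(img, [BinaryMask(m1), BinaryMask(~m1)])
        assert len(parts) == 3
        total = sum(p.voxels for p in parts)
        assert np.array_equal(total, img.voxels)
        assert not parts[2].voxels.any()

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(img=stacks, m1=masks, m2=masks)
    def test_outputs_disjoint_and_sum_to_input(self, img, m1, m2):
        parts = separate(img, [m1, m2])
        total = sum(p.voxels for p in parts)
        assert np.array_equal(total, img.voxels)
        for i in range(len(parts)):
            for j in range(i + 1, len(parts)):
                assert not ((parts[i].voxels != 0) & (parts[j].voxels != 0)).any()


class TestTraceSeparated:
    def test_overlapping_pair_with_oracle_mask(self):
        from arborsplit.synthetic import (
            SynthParams,
            arbor_subtree,
            mask_from_tree,
            overlapping_pair,
            render,
        )

        p = SynthParams(seed=1)
        tree_a, _, combined = overlapping_pair(p)
        img = render(combined, p)
        bif = int(tree_a.metadata["bifurcation_id"])
        mask = mask_from_tree(arbor_subtree(tree_a, bif), min(p.spacing), p)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = trace_separated(img, [mask], TraceConfig())
        origins = {int(o) for o in t.metadata["node_origin_partial"].split(",")}
        assert len(origins) >= 2  # nodes from both partial images present
        assert sum(n.parent_id == -1 for n in t.nodes) == 1

    def test_revised_beats_basic_on_overlap(self):
        from arborsplit.synthetic import (
            SynthParams,
            arbor_subtree,
            mask_from_tree,
            overlapping_pair,
            render,
        )

        p = SynthParams(seed=2)
        tree_a, _, combined = overlapping_pair(p)
        img = render(combined, p)
        bif = int(tree_a.metadata["bifurcation_id"])
        mask = mask_from_tree(arbor_subtree(tree_a, bif), min(p.spacing), p)
        basic = trace_stack(img, TraceConfig())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            revised = trace_separated(img, [mask], TraceConfig())
        assert diadem_score(revised, combined).score > diadem_score(basic, combined).score

    def test_mask_isolating_sole_arbor_consistent_with_plain_trace(self):
        from arborsplit.synthetic import SynthParams, mask_from_tree, random_tree, render

        p = SynthParams(seed=5)
        gold = random_tree(p)
        img = render(gold, p)
        mask = mask_from_tree(gold, 1.0, p)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sep = trace_separated(img, [mask], TraceConfig())
        plain = trace_stack(img, TraceConfig())
        assert abs(
            diadem_score(sep, gold).score - diadem_score(plain, gold).score
        ) <= 0.02

    def test_empty_second_partial_warns_and_uses_first(self):
        v = np.zeros((6, 8, 40))
        v[3, 3:6, 2:38] = 200.0
        img = ImageStack(v, spacing=(1.0, 1.0, 1.0))
        mask = BinaryMask(np.ones(v.shape, dtype=bool), spacing=img.spacing)
        with pytest.warns(UserWarning, match="skipped"):
            t = trace_separated(img, [mask], TraceConfig(threshold=100.0))
        assert len(t) > 1
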