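import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from ctibench.dataset_builder import (
    NegativeSamplingSpec,
    build_negative_set,
    filter_lrb,
    filter_rrb,
    generate_negatives,
    morgan_fingerprint,
    rotatable_bond_profile,
    tanimoto_similarity,
)

from conftest import make_record


class TestTanimoto:
    def test_identical_sets_are_one(self):
        fp = np.zeros(16)
        fp[[0, 3, 7]] = 1
        assert tanimoto_similarity(fp, fp) == 1.0

    def test_disjoint_sets_are_zero(self):
        a, b = np.zeros(16), np.zeros(16)
        a[[0, 1]] = 1
        b[[2, 3]] = 1
        assert tanimoto_similarity(a, b) == 0.0

    def test_partial_overlap(self):
        a, b = np.zeros(16), np.zeros(16)
        a[[1, 2, 3]] = 1
        b[[2, 3, 4]] = 1
        assert tanimoto_similarity(a, b) == 0.5  # |{2,3}| / |{1,2,3,4}|

    def test_both_empty_defined_as_one(self):
        assert tanimoto_similarity(np.zeros(8), np.zeros(8)) == 1.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            tanimoto_similarity(np.zeros(8), np.zeros(16))

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.booleans(), min_size=1, max_size=64), st.data())
    def test_matches_set_arithmetic(self, bits_a, data):
        bits_b = data.draw(
            st.lists(st.booleans(), min_size=len(bits_a), max_size=len(bits_a))
        )
        a, b = np.array(bits_a), np.array(bits_b)
        sa = {i for i, v in enumerate(bits_a) if v}
        sb = {i for i, v in enumerate(bits_b) if v}
        expected = len(sa & sb) / len(sa | sb) if (sa | sb) else 1.0
        assert tanimoto_similarity(a, b) == pytest.approx(expected)

    def test_agrees_with_chemistry_backend(self):
        """Independent cross-check on real molecules."""
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        for s1, s2 in [("CCO", "CCN"), ("c1ccccc1", "c1ccccc1C"), ("CCCC", "CC")]:
            bv1 = gen.GetFingerprint(Chem.MolFromSmiles(s1))
            bv2 = gen.GetFingerprint(Chem.MolFromSmiles(s2))
            expected = DataStructs.TanimotoSimilarity(bv1, bv2)
            ours = tanimoto_similarity(
                morgan_fingerprint(s1), morgan_fingerprint(s2)
            )
            assert ours == pytest.approx(expected)


def _fps_with_similarity(shared_total):
    """Candidate fingerprints with exact Tanimoto to one 10-bit binder.

    Each candidate shares ``shared`` of the binder's bits 0..9 and owns
    ``total - shared`` private bits, so Tanimoto = shared / (10 + total - shared).
    """
    binder = np.zeros(64)
    binder[:10] = 1
    fps = {"binder": binder}
    for idx, (shared, total) in enumerate(shared_total):
        fp = np.zeros(64)
        fp[:shared] = 1
        off = 10 + idx * 12
        fp[off : off + total - shared] = 1
        fps[f"cand{idx}"] = fp
        expected = shared / (10 + total - shared)
        assert tanimoto_similarity(binder, fp) == pytest.approx(expected)
    return fps


# (shared, total) pairs giving Tanimoto 0.9, 0.1 and 0.5 to the binder
_SPEC_EXAMPLE = [(9, 9), (2, 12), (5, 5)]


class TestGenerateNegatives:
    def test_most_dissimilar_candidate_selected(self):
        fps = _fps_with_similarity(_SPEC_EXAMPLE)  # Tanimoto 0.9, 0.1, 0.5
        negs = generate_negatives(
            "T",
            [("binder", "")],
            [("cand0", ""), ("cand1", ""), ("cand2", "")],
            NegativeSamplingSpec(k=1),
            fingerprints=fps,
        )
        assert [n.compound_id for n in negs] == ["cand1"]

    def test_k2_rank_order(self):
        fps = _fps_with_similarity(_SPEC_EXAMPLE)
        negs = generate_negatives(
            "T",
            [("binder", "")],
            [("cand0", ""), ("cand1", ""), ("cand2", "")],
            NegativeSamplingSpec(k=2),
            fingerprints=fps,
        )
        assert [n.compound_id for n in negs] == ["cand1", "cand2"]

    def test_candidate_identical_to_binder_ranked_last(self):
        fps = _fps_with_similarity([(5, 5)])
        fps["twin"] = fps["binder"].copy()
        negs = generate_negatives(
            "T",
            [("binder", "")],
            [("twin", ""), ("cand0", "")],
            NegativeSamplingSpec(k=1),
            fingerprints=fps,
        )
        assert [n.compound_id for n in negs] == ["cand0"]

    def test_k_exceeding_candidates_errors(self):
        fps = _fps_with_similarity([(5, 5)])
        with pytest.raises(ValueError, match="exceeds"):
            generate_negatives(
                "T", [("binder", "")], [("cand0", "")],
                NegativeSamplingSpec(k=2), fingerprints=fps,
            )

    def test_empty_binder_set_errors(self):
        with pytest.raises(ValueError, match="binder"):
            generate_negatives("T", [], [("c", "CC")], NegativeSamplingSpec(k=1))

    def test_matches_brute_force_oracle_on_random_instances(self):
        """Exhaustive max-min evaluation agrees with the implementation."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            m = int(rng.integers(1, 31))
            n = int(rng.integers(1, 31))
            k = int(rng.integers(1, n + 1))
            fps = {}
            binders = []
            for i in range(m):
                fps[f"b{i:02d}"] = (rng.random(32) < 0.3).astype(float)
                binders.append((f"b{i:02d}", ""))
            candidates = []
            for i in range(n):
                fps[f"c{i:02d}"] = (rng.random(32) < 0.3).astype(float)
                candidates.append((f"c{i:02d}", ""))
            # oracle: score every candidate by brute force, sort, take k
            oracle = []
            for cid, _ in candidates:
                dist = min(
                    1 - tanimoto_similarity(fps[bid], fps[cid]) for bid, _ in binders
                )
                oracle.append((dist, cid))
            oracle.sort(key=lambda t: (-t[0], t[1]))
            expected = [cid for _, cid in oracle[:k]]
            negs = generate_negatives(
                "T", binders, candidates, NegativeSamplingSpec(k=k), fingerprints=fps
            )
            assert [x.compound_id for x in negs] == expected

    def test_dataset_negatives_never_duplicate_positives(self, small_dataset):
        compounds, _, records = small_dataset
        positives = [r for r in records if r.label == 1][:30]
        all_cmpds = [(f"C{i:04d}", s) for i, s in enumerate(compounds)]
        negs = build_negative_set(positives, all_cmpds, NegativeSamplingSpec(k=2))
        pos_pairs = {(r.compound_id, r.target_id) for r in positives}
        neg_pairs = {(r.compound_id, r.target_id) for r in negs}
        assert not (pos_pairs & neg_pairs)
        assert all(r.label == 0 for r in negs)

    def test_default_k_rule_gives_ratio_band(self, small_dataset):
        """Default k targets a negatives:positives ratio around 2.5."""
        compounds, _, records = small_dataset
        # cap binders per target so the candidate pool can supply 2.5x
        per_target: dict[str, list] = {}
        for r in records:
            if r.label == 1 and len(per_target.setdefault(r.target_id, [])) < 5:
                per_target[r.target_id].append(r)
        positives = [r for recs in per_target.values() for r in recs]
        all_cmpds = [(f"C{i:04d}", s) for i, s in enumerate(compounds)]
        negs = build_negative_set(positives, all_cmpds, NegativeSamplingSpec())
        ratio = len(negs) / len(positives)
        assert 1.9 <= ratio <= 3.0


class TestRotatableBonds:
    @pytest.mark.parametrize(
        "smiles,n_rot,n_bonds",
        [
            ("CCCC", 1, 3),      # butane: only the central C-C rotates
            ("C", 0, 0),          # no bonds at all
            ("c1ccccc1", 0, 6),   # ring bonds never rotate
            ("CC(=O)NC", 0, 4),   # amide bond excluded under strict counting
        ],
    )
    def test_profiles(self, smiles, n_rot, n_bonds):
        p = rotatable_bond_profile(smiles)
        assert (p.n_rotatable, p.n_bonds) == (n_rot, n_bonds)

    def test_rbf_convention(self):
        assert rotatable_bond_profile("C").rbf == 0.0
        assert rotatable_bond_profile("CCCC").rbf == pytest.approx(1 / 3)

    def test_unparseable_errors(self):
        with pytest.raises(ValueError):
            rotatable_bond_profile("((")


class TestRotatableBondFilters:
    def test_lrb_threshold_inclusive(self):
        ten = make_record("C0", "C" * 13)  # 12 bonds, 10 rotatable
        eleven = make_record("C1", "C" * 14)  # 11 rotatable
        assert rotatable_bond_profile(ten.smiles).n_rotatable == 10
        assert rotatable_bond_profile(eleven.smiles).n_rotatable == 11
        assert filter_lrb([ten, eleven]) == [ten]

    def test_rrb_threshold_inclusive(self):
        records = [make_record("C0", "CCCC")]  # rbf 1/3 > 0.184
        assert filter_rrb(records) == []
        assert filter_rrb(records, max_rbf=1 / 3) == records

    def test_rrb_rigid_compound_kept(self):
        records = [make_record("C0", "c1ccccc1")]
        assert filter_rrb(records) == records

    def test_empty_input(self):
        assert filter_lrb([]) == []
        assert filter_rrb([]) == []

    def test_idempotent_and_order_preserving(self, small_dataset):
        _, _, records = small_dataset
        once = filter_lrb(records)
        assert filter_lrb(once) == once
        positions = [records.index(r) for r in once]
        assert positions == sorted(positions)
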