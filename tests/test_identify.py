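import numpy as np
import pytest

from fragspec.chem import DEFAULT_ADDUCTS, POSITIVE, monoisotopic_mass, parse_structure
from fragspec.identify import (
    CandidateRecord,
    PrecursorQuery,
    filter_candidates,
    identify,
    jaccard_score,
    weighted_jaccard_score,
)
from fragspec.predict import predict
from fragspec.spectra import Peak, Spectrum
from fragspec.tolerance import MassTolerance

TOL = MassTolerance(abs_da=0.01, ppm=0.0)
GLUCOSE = "OCC1OC(O)C(O)C(O)C1O"


def spec_of(mzs, energy="low"):
    return Spectrum(energy, [Peak(m, 50.0) for m in mzs])


def test_filter_keeps_glucose_within_001():
    glucose = CandidateRecord.from_line("g", GLUCOSE)
    assert glucose.neutral_mass == pytest.approx(180.06339, abs=1e-5)
    query = PrecursorQuery(181.07066, [DEFAULT_ADDUCTS["[M+H]+"]], tol_da=0.01)
    assert filter_candidates([glucose], query) == [glucose]


def test_filter_half_dalton_regime_keeps_decoy():
    glucose = CandidateRecord.from_line("g", GLUCOSE)
    decoy = CandidateRecord("d", "X", neutral_mass=180.55)
    query = PrecursorQuery(181.07066, [DEFAULT_ADDUCTS["[M+H]+"]], tol_da=0.5)
    kept = filter_candidates([glucose, decoy], query)
    assert kept == [glucose, decoy]  # both inside +/-0.5 Da, order preserved


def test_filter_5ppm_regime_is_narrow():
    glucose = CandidateRecord.from_line("g", GLUCOSE)
    decoy = CandidateRecord("d", "X", neutral_mass=180.0650)
    query = PrecursorQuery(181.07066, [DEFAULT_ADDUCTS["[M+H]+"]], tol_ppm=5.0)
    assert filter_candidates([glucose, decoy], query) == [glucose]


def test_filter_empty_adducts_gives_empty():
    glucose = CandidateRecord.from_line("g", GLUCOSE)
    query = PrecursorQuery(181.07066, [], tol_da=0.5)
    assert filter_candidates([glucose], query) == []


def test_filter_respects_alternate_adducts():
    glucose = CandidateRecord.from_line("g", GLUCOSE)
    na_mz = 180.06339 + DEFAULT_ADDUCTS["[M+Na]+"].mass_delta
    query = PrecursorQuery(na_mz, [DEFAULT_ADDUCTS["[M+H]+"]], tol_da=0.01)
    assert filter_candidates([glucose], query) == []
    query_na = PrecursorQuery(
        na_mz, [DEFAULT_ADDUCTS["[M+H]+"], DEFAULT_ADDUCTS["[M+Na]+"]],
        tol_da=0.01)
    assert filter_candidates([glucose], query_na) == [glucose]


def test_jaccard_identical_is_one():
    s = spec_of([100.0, 200.0, 300.0])
    assert jaccard_score(s, s, TOL) == 1.0
    assert weighted_jaccard_score(s, s, TOL) == pytest.approx(1.0)


def test_jaccard_disjoint_is_zero():
    assert jaccard_score(spec_of([100.0, 200.0]), spec_of([150.0, 250.0]),
                         TOL) == 0.0


def test_jaccard_worked_example():
    """3 predicted, 3 observed, one match inside 0.01 Da:
    1 / (3 + 3 - 1) = 0.2."""
    predicted = spec_of([100.0000, 200.0000, 300.0000])
    observed = spec_of([100.0050, 200.2000, 400.0000])
    assert jaccard_score(predicted, observed, TOL) == pytest.approx(0.2)


def test_jaccard_matches_exhaustive_bipartite_oracle(rng):
    """Greedy closest-first matching gives the same cardinality as an
    exhaustive search over one-to-one matchings on small spectra."""
    import itertools

    for _ in range(20):
        a = sorted(rng.uniform(100, 110, 4))
        b = sorted(rng.uniform(100, 110, 4))
        sa, sb = spec_of(list(a)), spec_of(list(b))
        tol = MassTolerance(abs_da=0.5, ppm=0.0)
        # oracle: maximum matching size by brute force over permutations
        best = 0
        for perm in itertools.permutations(range(4)):
            size = sum(1 for i, j in enumerate(perm) if abs(a[i] - b[j]) <= 0.5)
            best = max(best, size)
        got = jaccard_score(sa, sb, tol)
        # greedy closest-first is not guaranteed maximum, but on interval
        # tolerance matching of sorted reals it attains it
        assert got == pytest.approx(best / (8 - best))


def test_jaccard_symmetric(rng):
    for _ in range(20):
        a = spec_of(sorted(rng.uniform(50, 500, 6)))
        b = spec_of(sorted(rng.uniform(50, 500, 5)))
        tol = MassTolerance(abs_da=1.0, ppm=0.0)
        assert jaccard_score(a, b, tol) == jaccard_score(b, a, tol)
        assert weighted_jaccard_score(a, b, tol) == pytest.approx(
            weighted_jaccard_score(b, a, tol))


def test_self_retrieval_trivial(tiny_library, ref_models):
    """A candidate list containing the true molecule, queried with that
    molecule's own predicted spectra, puts it at rank 1 with score 1."""
    true = tiny_library[0]
    spectra = predict(true, POSITIVE, ref_models)
    cands = [CandidateRecord.from_line(f"C{i}", m.canonical_key)
             for i, m in enumerate(tiny_library[:5])]
    ranked = identify(spectra, cands, POSITIVE, ref_models, TOL)
    assert ranked[0].ref_id == "C0"
    assert ranked[0].score == pytest.approx(1.0)
    assert ranked[0].rank == 1
    assert [r.rank for r in ranked] == list(range(1, len(cands) + 1))
    scores = [r.score for r in ranked]
    assert scores == sorted(scores, reverse=True)


def test_single_candidate_ranks_first(tiny_library, ref_models):
    spectra = predict(tiny_library[0], POSITIVE, ref_models)
    cands = [CandidateRecord.from_line("only", tiny_library[1].canonical_key)]
    ranked = identify(spectra, cands, POSITIVE, ref_models, TOL)
    assert len(ranked) == 1 and ranked[0].rank == 1


def test_candidate_cap_is_hard_error(tiny_library, ref_models):
    spectra = predict(tiny_library[0], POSITIVE, ref_models)
    cands = [CandidateRecord(f"c{i}", "C", neutral_mass=16.0)
             for i in range(101)]
    with pytest.raises(ValueError, match="100"):
        identify(spectra, cands, POSITIVE, ref_models, TOL)


def test_unparsable_candidate_scores_zero_with_warning(tiny_library, ref_models):
    spectra = predict(tiny_library[0], POSITIVE, ref_models)
    cands = [CandidateRecord.from_line("good", tiny_library[0].canonical_key),
             CandidateRecord.from_line("bad", "xx(")]
    with pytest.warns(UserWarning, match="bad"):
        ranked = identify(spectra, cands, POSITIVE, ref_models, TOL)
    by_id = {r.ref_id: r for r in ranked}
    assert by_id["bad"].score == 0.0
    assert by_id["bad"].parse_failed


def test_adding_candidate_preserves_relative_order(tiny_library, ref_models):
    spectra = predict(tiny_library[0], POSITIVE, ref_models)
    base = [CandidateRecord.from_line(f"C{i}", m.canonical_key)
            for i, m in enumerate(tiny_library[:4])]
    extra = base + [CandidateRecord.from_line("C9", tiny_library[5].canonical_key)]
    order_base = [r.ref_id for r in identify(spectra, base, POSITIVE,
                                             ref_models, TOL)]
    order_extra = [r.ref_id for r in identify(spectra, extra, POSITIVE,
                                              ref_models, TOL)]
    assert [r for r in order_extra if r != "C9"] == order_base


def test_ranking_matches_brute_force_recomputation(tiny_library, ref_models):
    """Independent rescoring: recompute each candidate's energy-averaged
    Jaccard directly and compare the induced ranking."""
    spectra = predict(tiny_library[2], POSITIVE, ref_models)
    cands = [CandidateRecord.from_line(f"C{i}", m.canonical_key)
             for i, m in enumerate(tiny_library[:3])]
    ranked = identify(spectra, cands, POSITIVE, ref_models, TOL)
    manual = []
    for c in cands:
        pred = predict(c.mol, POSITIVE, ref_models)
        score = np.mean([jaccard_score(pred[e], spectra[e], TOL)
                         for e in ("low", "medium", "high")])
        manual.append((-score, c.ref_id))
    expected_order = [rid for _, rid in sorted(manual)]
    assert [r.ref_id for r in ranked] == expected_order
    for r, (neg, _) in zip(ranked, sorted(manual)):
        assert r.score == pytest.approx(-neg)


def test_top_k_truncates(tiny_library, ref_models):
    spectra = predict(tiny_library[0], POSITIVE, ref_models)
    cands = [CandidateRecord.from_line(f"C{i}", m.canonical_key)
             for i, m in enumerate(tiny_library[:6])]
    ranked = identify(spectra, cands, POSITIVE, ref_models, TOL, top_k=2)
    assert [r.rank for r in ranked] == [1, 2]
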