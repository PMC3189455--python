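"""Residual profiles: locality, sparsity, antisymmetry, batch features."""

import numpy as np
import pytest

from fourbody import (
    MutantRecord,
    SyntheticSpec,
    all_single_site_mutations,
    feature_matrix,
    generate_trace,
    mutant_profile,
    neighbors,
    quadruplet_composition,
    read_feature_matrix,
    read_mutant_list,
    residual_profile,
    residue_environment_scores,
    tessellate,
    write_feature_matrix,
    write_mutant_list,
)


def brute_environment_scores(tess, labels, table):
    """Independent recomputation: per-position sum of simplex scores."""
    out = np.zeros(tess.n_points)
    for pos in range(1, tess.n_points + 1):
        for s in tess.simplices:
            if pos in s.vertices:
                out[pos - 1] += table.score([labels[v - 1] for v in s.vertices])
    return out


def test_single_simplex_scores(single_simplex, table):
    """All four residues of a one-simplex structure share the simplex's q."""
    tess = tessellate(single_simplex)
    q = table.score(("A", "C", "D", "E"))
    prof = residue_environment_scores(tess, single_simplex.sequence(), table)
    assert np.allclose(prof.scores, q)


def test_tetrahedron_centroid_incidence(table):
    """Centroid sums all 4 simplices; each outer vertex its 3 incident ones."""
    from conftest import make_trace

    v = 10.0 * np.array(
        [[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
         [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3)]]
    )
    trace = make_trace(np.vstack([v, v.mean(axis=0)]), "ACDEF")
    tess = tessellate(trace)
    prof = residue_environment_scores(tess, trace.sequence(), table)
    per_simplex = {
        s.vertices: table.score(quadruplet_composition(tess, trace, s))
        for s in tess.simplices
    }
    assert prof.scores[4] == pytest.approx(sum(per_simplex.values()))
    for outer in range(1, 5):
        expected = sum(q for verts, q in per_simplex.items() if outer in verts)
        assert prof.scores[outer - 1] == pytest.approx(expected)


def test_scores_match_brute_force(target_trace, target_tess, table):
    labels = list(target_trace.sequence())
    prof = residue_environment_scores(target_tess, labels, table)
    assert np.allclose(prof.scores, brute_environment_scores(target_tess, labels, table))


def test_cutoff_excluded_position_scores_zero(target_trace, table):
    tess = tessellate(target_trace, cutoff=4.0)  # aggressive cutoff
    prof = residue_environment_scores(tess, target_trace.sequence(), table)
    covered = {v for s in tess.simplices for v in s.vertices}
    for pos in range(1, len(target_trace) + 1):
        if pos not in covered:
            assert prof.scores[pos - 1] == 0.0
    assert len(covered) < len(target_trace)


def test_mutant_record_validation(target_trace):
    with pytest.raises(ValueError):
        MutantRecord(1, "A", "A")  # identity substitution
    with pytest.raises(ValueError):
        MutantRecord(1, "B", "C")  # nonstandard type
    wt = target_trace.residues[9].aa
    other = "A" if wt != "A" else "C"
    bad = MutantRecord(10, other, "W" if other != "W" else "Y")
    with pytest.raises(ValueError, match="mismatch"):
        bad.validate_against(target_trace)


def test_mutant_profile_changes_only_incident_simplices(
    target_trace, target_tess, table
):
    """Only simplices with the mutated vertex change their contribution, so
    the profile differs from wild type exactly on the mutated position and
    its nearest neighbors."""
    wt_prof = residue_environment_scores(target_tess, target_trace.sequence(), table)
    pos = 30
    wt = target_trace.residues[pos - 1].aa
    mut = "A" if wt != "A" else "C"
    m = MutantRecord(pos, wt, mut)
    mprof = mutant_profile(target_tess, target_trace, table, m)
    res = residual_profile(wt_prof, mprof, m)
    support = set(np.flatnonzero(res.ec_scores) + 1)
    assert support <= {pos} | neighbors(target_tess, pos)
    # and the mutant profile equals a from-scratch recomputation on the
    # relabeled sequence (frozen tessellation)
    labels = list(target_trace.sequence())
    labels[pos - 1] = mut
    assert np.allclose(
        mprof.scores, brute_environment_scores(target_tess, labels, table)
    )


def test_residual_zero_for_identical_profiles(target_trace, target_tess, table):
    prof = residue_environment_scores(target_tess, target_trace.sequence(), table)
    wt = target_trace.residues[0].aa
    m = MutantRecord(1, wt, "A" if wt != "A" else "C")
    res = residual_profile(prof, prof, m)
    assert np.all(res.ec_scores == 0)


def test_sparsity_exhaustive_small_structure(table):
    """Every one of the 19N mutants of a small structure has EC support
    within {position} ∪ neighbors(position)."""
    trace = generate_trace(SyntheticSpec(n_residues=15, seed=21))
    tess = tessellate(trace)
    X, _ = feature_matrix(trace, tess, table, all_single_site_mutations(trace))
    for row, m in zip(X, all_single_site_mutations(trace)):
        support = set(np.flatnonzero(row) + 1)
        assert support <= {m.position} | neighbors(tess, m.position)


def test_ec_at_mutated_position_matches_incident_sum(
    target_trace, target_tess, table
):
    """EC score at the mutated site equals the sum over incident simplices
    of q(new composition) - q(old composition)."""
    pos = 12
    wt = target_trace.residues[pos - 1].aa
    mut = "G" if wt != "G" else "A"
    m = MutantRecord(pos, wt, mut)
    X, _ = feature_matrix(target_trace, target_tess, table, [m])
    expected = 0.0
    labels = list(target_trace.sequence())
    for s in target_tess.incidence()[pos]:
        old = [labels[v - 1] for v in s.vertices]
        new = [mut if v == pos else labels[v - 1] for v in s.vertices]
        expected += table.score(new) - table.score(old)
    assert X[0, pos - 1] == pytest.approx(expected)


def test_antisymmetry(target_trace, target_tess, table):
    """A→B on the wild type negates B→A computed on the A-relabeled frame."""
    from fourbody.structures import CAlphaTrace, ResiduePoint

    pos = 20
    wt = target_trace.residues[pos - 1].aa
    mut = "K" if wt != "K" else "R"
    fwd, _ = feature_matrix(
        target_trace, target_tess, table, [MutantRecord(pos, wt, mut)]
    )
    swapped = CAlphaTrace(
        "A",
        [
            ResiduePoint(r.seq_index, r.residue_id, mut if r.seq_index == pos else r.aa, r.coord)
            for r in target_trace.residues
        ],
    )
    rev, _ = feature_matrix(
        swapped, target_tess, table, [MutantRecord(pos, mut, wt)]
    )
    assert np.allclose(fwd[0], -rev[0])


def test_feature_matrix_shapes_and_errors(target_trace, target_tess, table):
    muts = all_single_site_mutations(target_trace)[:3]
    X, y = feature_matrix(target_trace, target_tess, table, muts)
    assert X.shape == (3, len(target_trace))
    assert list(y) == [0, 0, 0]
    X0, y0 = feature_matrix(target_trace, target_tess, table, [])
    assert X0.shape[0] == 0 and y0.shape == (0,)
    wt = target_trace.residues[4].aa
    bad = MutantRecord(5, "A" if wt != "A" else "C", "Y" if wt != "Y" else "W")
    with pytest.raises(ValueError, match="#1"):
        feature_matrix(target_trace, target_tess, table, [muts[0], bad])


def test_same_position_different_substitutions_differ(
    target_trace, target_tess, table
):
    pos = 8
    wt = target_trace.residues[pos - 1].aa
    subs = [aa for aa in "ACDE" if aa != wt][:2]
    X, _ = feature_matrix(
        target_trace, target_tess, table,
        [MutantRecord(pos, wt, s) for s in subs],
    )
    assert not np.allclose(X[0], X[1])


def test_mutant_list_round_trip(target_trace):
    muts = [
        MutantRecord(1, target_trace.residues[0].aa,
                     "A" if target_trace.residues[0].aa != "A" else "C", 1),
        MutantRecord(2, target_trace.residues[1].aa,
                     "W" if target_trace.residues[1].aa != "W" else "Y", -1),
        MutantRecord(3, target_trace.residues[2].aa,
                     "G" if target_trace.residues[2].aa != "G" else "A", 0),
    ]
    back = read_mutant_list(write_mutant_list(muts))
    assert back == muts


def test_mutant_list_parse_errors():
    with pytest.raises(ValueError, match="line 2"):
        read_mutant_list("1 A C +1\n2 A C maybe\n")
    with pytest.raises(ValueError, match="line 1"):
        read_mutant_list("1 A A +1\n")


def test_feature_matrix_text_round_trip(target_trace, target_tess, table):
    muts = all_single_site_mutations(target_trace)[:5]
    X, _ = feature_matrix(target_trace, target_tess, table, muts)
    X2, muts2 = read_feature_matrix(write_feature_matrix(X, muts, "target"))
    assert muts2 == muts
    assert np.allclose(X, X2, atol=1e-8)
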