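"""PAM scanning, percentile ranking and off-target screening vs oracles."""

import numpy as np
import pandas as pd
import pytest

from kshred.targets import (
    BackgroundIndex,
    SelectionParams,
    offtarget_screen,
    pam_scan_cas9,
    pam_scan_cas12a,
    percentile_filter,
    rank_targets,
)

from _oracles import offtarget_counts, pam_sites_cas9, pam_sites_cas12a, revcomp


def _rand_kmer(rng, n=25, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), n))


def test_cas9_all_g_kmer_has_three_forward_placements():
    placements = pam_scan_cas9("G" * 25)
    assert len(placements) == 3
    assert {p.strand for p in placements} == {"+"}
    assert sorted(p.offset for p in placements) == [0, 1, 2]
    assert all(len(p.protospacer) == 20 and p.pam.endswith("GG") for p in placements)


def test_cas9_all_a_kmer_has_no_placement():
    assert pam_scan_cas9("A" * 25) == []


def test_cas12a_all_t_kmer_has_no_placement():
    assert pam_scan_cas12a("T" * 25) == []


def test_cas12a_ttta_prefix_single_forward_placement():
    kmer = "TTTA" + "A" * 21
    placements = pam_scan_cas12a(kmer)
    # reverse strand is T{21}TAAA: its only TTT runs lack a V base in range
    fwd = [p for p in placements if p.strand == "+"]
    assert len(fwd) == 1
    assert fwd[0].offset == 4 and fwd[0].pam == "TTTA" and fwd[0].protospacer == "A" * 21


def test_pam_scanners_match_oracle_on_random_kmers():
    rng = np.random.default_rng(0)
    # T-rich alphabet makes Cas12a PAMs common enough to exercise
    for i in range(1000):
        kmer = _rand_kmer(rng, 25, "ACGT" if i % 2 else "ATTG")
        got9 = {(p.strand, p.offset, p.protospacer, p.pam) for p in pam_scan_cas9(kmer)}
        assert got9 == set(pam_sites_cas9(kmer))
        got12 = {(p.strand, p.offset, p.protospacer, p.pam) for p in pam_scan_cas12a(kmer)}
        assert got12 == set(pam_sites_cas12a(kmer))


def test_cas12a_placement_count_bounded():
    rng = np.random.default_rng(1)
    for _ in range(200):
        kmer = _rand_kmer(rng, 25, "ATG")
        per_strand = {"+": 0, "-": 0}
        for p in pam_scan_cas12a(kmer):
            per_strand[p.strand] += 1
        assert max(per_strand.values()) <= 2


def _stats_frame(rng, n):
    codes = np.sort(rng.choice(2**40, n, replace=False).astype(np.uint64))
    df = pd.DataFrame(
        {
            "sum": rng.integers(100, 10_000, n),
            "hits_sum": rng.integers(1, 2_000, n),
            "max_pt": rng.integers(1, 60, n),
            "unique_bin_occurrence": rng.integers(1, 300, n),
            "xsi": 1.0,
        },
        index=pd.Index(codes, name="code"),
    )
    df.attrs["k"] = 25
    return df


def test_percentile_rank_cut():
    """N=10000 at q=0.05% cuts each criterion at rank ceil(0.0005*N) = 5."""
    rng = np.random.default_rng(2)
    n = 10_000
    codes = np.sort(rng.choice(2**40, n, replace=False).astype(np.uint64))
    order = rng.permutation(n)
    vals = (10_000 - order).astype(np.int64)  # all four criteria fully correlated
    df = pd.DataFrame(
        {"sum": vals, "hits_sum": vals, "max_pt": vals, "unique_bin_occurrence": vals, "xsi": 1.0},
        index=pd.Index(codes, name="code"),
    )
    df.attrs["k"] = 25
    flagged = percentile_filter(df, SelectionParams(q=0.0005, top_n=5))
    assert len(flagged) == 5
    assert set(flagged["sum"]) == {10_000, 9_999, 9_998, 9_997, 9_996}
    assert list(flagged["rank"]) == [1, 2, 3, 4, 5]
    # rank-sum ordering is by the statistics, best first
    assert list(flagged["sum"]) == sorted(flagged["sum"], reverse=True)


def test_percentile_q_one_flags_everything():
    rng = np.random.default_rng(3)
    df = _stats_frame(rng, 500)
    flagged = percentile_filter(df, SelectionParams(q=1.0, top_n=1))
    assert len(flagged) == len(df)


def test_percentile_tie_breaking_is_lexicographic():
    codes = np.array([7, 3, 11], np.uint64)
    df = pd.DataFrame(
        {
            "sum": [10, 10, 10],
            "hits_sum": [5, 5, 5],
            "max_pt": [2, 2, 2],
            "unique_bin_occurrence": [3, 3, 3],
            "xsi": 1.0,
        },
        index=pd.Index(codes, name="code"),
    )
    df.attrs["k"] = 25
    flagged = percentile_filter(df, SelectionParams(q=1.0))
    # identical statistics: order resolved by k-mer string
    assert list(flagged["kmer_str"]) == sorted(flagged["kmer_str"])
    assert (flagged["rank_sum"] == flagged["rank_sum"].iloc[0]).all()


def test_percentile_empty_input_warns():
    df = pd.DataFrame(
        columns=["sum", "hits_sum", "max_pt", "unique_bin_occurrence", "xsi"],
        index=pd.Index(np.array([], np.uint64), name="code"),
    )
    with pytest.warns(UserWarning, match="empty"):
        flagged = percentile_filter(df, SelectionParams())
    assert len(flagged) == 0


def test_offtarget_plant_and_count():
    rng = np.random.default_rng(4)
    proto = _rand_kmer(rng, 20)
    bg = _rand_kmer(rng, 400) + proto + _rand_kmer(rng, 400)
    counts = offtarget_screen(proto, [bg], max_mm=3)
    assert counts[0] == 1
    variant = "A" + proto[1:] if proto[0] != "A" else "C" + proto[1:]
    counts = offtarget_screen(proto, [_rand_kmer(rng, 100) + variant], max_mm=3)
    assert counts[0] == 0 and counts[1] == 1
    # reverse-strand copies are found too
    counts = offtarget_screen(proto, [revcomp(proto)], max_mm=0)
    assert counts[0] == 1


def test_offtarget_empty_background_warns():
    with pytest.warns(UserWarning, match="empty"):
        counts = offtarget_screen("A" * 20, [], max_mm=3)
    assert counts.tolist() == [0, 0, 0, 0]


def test_offtarget_scan_and_index_match_oracle():
    rng = np.random.default_rng(5)
    for trial in range(40):
        # small alphabet so mismatch neighbours actually occur
        alphabet = "AC" if trial % 2 else "ACG"
        proto = _rand_kmer(rng, 20, alphabet)
        seqs = [_rand_kmer(rng, int(rng.integers(10, 300)), alphabet) for _ in range(8)]
        expected = offtarget_counts(proto, seqs, 3)
        assert offtarget_screen(proto, seqs, 3).tolist() == expected
        assert BackgroundIndex(seqs).count(proto, 3).tolist() == expected


def test_background_index_query_length_guard():
    with pytest.raises(ValueError, match="too short"):
        BackgroundIndex(["ACGT" * 30]).count("ACGTACGTACGTACG", 3)


def _flagged_for_ranking():
    rows = []
    kmers = {
        # has a forward Cas9 PAM (GG at positions 21-22)
        "with_pam": "ACGTACGTACGTACGTACGTAGGAC",
        "no_pam": "A" * 25,
    }
    for i, (name, kmer) in enumerate(kmers.items()):
        from kshred._encode import canonical_code

        rows.append(
            {
                "code": canonical_code(kmer),
                "kmer_str": kmer,
                "sum": 1000 - i,
                "hits_sum": 500,
                "max_pt": 30,
                "unique_bin_occurrence": 80,
                "xsi": 1.0,
                "rank": i + 1,
            }
        )
    df = pd.DataFrame(rows).set_index("code")
    df.attrs["k"] = 25
    return df, kmers


def test_rank_targets_drops_candidates_without_placement():
    df, kmers = _flagged_for_ranking()
    with pytest.warns(UserWarning, match="survived"):
        table = rank_targets(df, None, SelectionParams(top_n=25))
    assert set(table["kmer"]) == {kmers["with_pam"]}
    assert (table["selected"]).all()


def test_rank_targets_excludes_near_offtargets():
    df, kmers = _flagged_for_ranking()
    proto = pam_scan_cas9(kmers["with_pam"])[0].protospacer
    # a 2-mismatch background neighbour excludes the placement
    neighbour = list(proto)
    neighbour[0] = "T" if neighbour[0] != "T" else "G"
    neighbour[10] = "T" if neighbour[10] != "T" else "G"
    bg = BackgroundIndex(["C" * 50 + "".join(neighbour) + "C" * 50])
    with pytest.warns(UserWarning, match="survived"):
        table = rank_targets(df, bg, SelectionParams(top_n=25))
    assert kmers["with_pam"] not in set(table["kmer"]) or (
        table.loc[table["kmer"] == kmers["with_pam"], "offtarget_mm2"] == 0
    ).all()


def test_rank_targets_returns_top_n_rows():
    rng = np.random.default_rng(6)
    rows = []
    from kshred._encode import canonical_code

    n = 0
    while n < 40:
        kmer = _rand_kmer(rng, 25)
        if not pam_scan_cas9(kmer):
            continue
        rows.append(
            {
                "code": canonical_code(kmer),
                "kmer_str": kmer,
                "sum": 5000 - n,
                "hits_sum": 100,
                "max_pt": 10,
                "unique_bin_occurrence": 50,
                "xsi": 1.0,
                "rank": n + 1,
            }
        )
        n += 1
    df = pd.DataFrame(rows).set_index("code")
    df.attrs["k"] = 25
    table = rank_targets(df, None, SelectionParams(top_n=25))
    assert table["kmer"].nunique() == 25
    # deterministic order preserved from the flagged ranking
    assert (table.groupby("kmer", sort=False)["rank"].first().is_monotonic_increasing)
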