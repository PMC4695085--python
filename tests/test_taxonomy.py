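"""Unit tests for read QC and hierarchical taxonomy assignment."""

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from symcomm import taxonomy
from symcomm.alignment import global_identity, revcomp
from symcomm.taxonomy import (
    AmpliconRead,
    RefRecord,
    ReferenceDB,
    TaxonLabel,
    assign_clade,
    assign_subtype,
    build_count_table,
    cluster_denovo,
    filter_homopolymer,
    parse_label,
    quality_trim,
    trim_primers,
)


def read_of(seq, quals=None, rid="r1", sample="s1"):
    return AmpliconRead(rid, seq, None if quals is None else tuple(quals),
                        sample)


# ---------------------------------------------------------------------------
# quality trimming


def oracle_quality_trim_length(quals, q, window):
    """Brute-force scan over all trailing windows: keep through the last
    position whose trailing window mean is >= q."""
    cut = 0
    for i in range(len(quals)):
        win = quals[max(0, i - window + 1): i + 1]
        if sum(win) / len(win) >= q:
            cut = i + 1
    return cut


def test_quality_trim_high_quality_read_unchanged():
    r = read_of("A" * 100, [40] * 100)
    assert quality_trim(r, 25, 10).sequence == r.sequence


def test_quality_trim_low_quality_read_emptied():
    r = read_of("ACGT" * 25, [10] * 100)
    assert quality_trim(r, 25, 10).sequence == ""


@pytest.mark.parametrize("seed", range(5))
def test_quality_trim_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, 120))
    quals = list(rng.integers(2, 41, size=n))
    seq = "".join(rng.choice(list("ACGT"), size=n))
    for window in (5, 10):
        got = quality_trim(read_of(seq, quals), 25, window)
        want = oracle_quality_trim_length(quals, 25, window)
        assert len(got.sequence) == want
        assert got.sequence == seq[:want]


def test_quality_trim_drop_then_recover_profile():
    # 50 high-quality bases then a low tail: trimmed where the trailing
    # mean first stays below Q25
    quals = [40] * 50 + [2] * 50
    seq = "AC" * 50
    got = quality_trim(read_of(seq, quals), 25, 10)
    assert len(got.sequence) == oracle_quality_trim_length(quals, 25, 10)
    assert 50 <= len(got.sequence) < 60  # a few tail bases ride the window


def test_quality_trim_without_qualities_passes_through():
    r = read_of("ACGTACGT")
    assert quality_trim(r) is r


# ---------------------------------------------------------------------------
# homopolymer filter


@pytest.mark.parametrize("seq,keep", [
    ("ACGTACGT", True),
    ("ACG" + "A" * 7 + "CGT", False),  # run of 7 discarded
    ("ACG" + "A" * 6 + "CGT", True),   # run of 6 is not >6
])
def test_homopolymer_filter_boundary(seq, keep):
    assert filter_homopolymer(read_of(seq)) is keep


# ---------------------------------------------------------------------------
# primer trimming


FWD = "GTGAATTGCAGAACTCCGTG"
REV = "CCTCCGCTTACTTATATGCTT"


def oracle_semiglobal_distance(pattern, text):
    """Full DP (Wagner-Fischer with free start/end in text) returning
    the best edit distance of pattern against any text substring."""
    m, n = len(pattern), len(text)
    prev = [0] * (n + 1)  # free start
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = 0 if pattern[i - 1] == text[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)


def test_trim_primers_exact_match_recovers_insert():
    insert = "ACGTTGCA" * 10
    r = read_of(FWD + insert + revcomp(REV))
    out = trim_primers(r, FWD, REV)
    assert out.sequence == insert


def test_trim_primers_rejects_four_mismatches():
    bad = FWD[:5] + "C" + FWD[6:8] + "G" + FWD[9:11] + "T" + FWD[12:14] + "A" + FWD[15:]
    assert sum(a != b for a, b in zip(bad, FWD)) == 4
    assert oracle_semiglobal_distance(bad, FWD) == 4
    insert = "ACGTTGCA" * 10
    r = read_of(bad + insert + revcomp(REV))
    assert trim_primers(r, FWD, REV, max_errors=3) is None


def test_trim_primers_three_edits_accepted_and_span_verified():
    # 2 substitutions + 1 insertion = 3 edits in the forward primer
    mutated = FWD[:5] + "C" + FWD[6:11] + "T" + FWD[12:15] + "G" + FWD[15:]
    assert FWD[5] != "C" and FWD[11] != "T"
    assert oracle_semiglobal_distance(FWD, mutated) == 3
    insert = "TTGCAACG" * 10
    r = read_of(mutated + insert + revcomp(REV))
    out = trim_primers(r, FWD, REV, max_errors=3)
    assert out is not None
    assert out.sequence == insert


def test_trim_primers_missing_reverse_trims_forward_only():
    insert = "ACGTTGCA" * 10
    r = read_of(FWD + insert)
    out = trim_primers(r, FWD, REV)
    assert out.sequence == insert


def test_trim_primers_iupac_ambiguity_matches():
    primer = "GTGAATTGCAGRACTCCGTG"  # R matches A or G
    insert = "TTGCAACG" * 10
    r = read_of(FWD + insert + revcomp(REV))
    out = trim_primers(r, primer, REV, max_errors=0)
    assert out.sequence == insert


# ---------------------------------------------------------------------------
# clade assignment


def test_assign_clade_exact_reference_match(toy_db):
    db, _ = toy_db
    for rec in (db.by_clade["C"][0], db.by_clade["A"][0]):
        call = assign_clade(rec.sequence, db)
        assert call.clade == rec.clade
        assert call.log10_e < -20


def test_assign_clade_midpoint_sequence_unassigned(toy_db):
    # equidistant between a clade A and a clade C reference: the
    # next-best ratio rule must leave it unassigned
    db, _ = toy_db
    a = db.by_clade["A"][0].sequence
    c = db.by_clade["C"][0].sequence
    assert len(a) == len(c)
    diffs = [i for i in range(len(a)) if a[i] != c[i]]
    mid = list(a)
    for j, i in enumerate(diffs):
        if j % 2 == 0:
            mid[i] = c[i]
    mid = "".join(mid)
    d_a = sum(x != y for x, y in zip(mid, a))
    d_c = sum(x != y for x, y in zip(mid, c))
    assert abs(d_a - d_c) <= 1
    assert assign_clade(mid, db).clade is None


def test_assign_clade_random_sequence_unassigned(toy_db):
    db, _ = toy_db
    rng = np.random.default_rng(3)
    for _ in range(5):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        assert assign_clade(seq, db).clade is None


def test_assign_clade_empty_read_unassigned(toy_db):
    db, _ = toy_db
    assert assign_clade("", db).clade is None


# ---------------------------------------------------------------------------
# subtype assignment


def test_assign_subtype_exact_copy_returns_leaf(toy_db):
    db, _ = toy_db
    rec = db.by_clade["C"][0]
    label = assign_subtype(rec.sequence, "C", db)
    assert label == TaxonLabel("leaf", "C", rec.name)


def test_assign_subtype_divergent_read_is_new(toy_db):
    db, truth = toy_db
    clade, seq = truth.novel["Cx1"]  # <97% identical to every C reference
    label = assign_subtype(seq, clade, db)
    assert label.kind == "new"


def test_assign_subtype_missing_clade_raises(toy_db):
    db, _ = toy_db
    with pytest.raises(ValueError):
        assign_subtype("ACGT" * 80, "Z", db)


def _lca_fixture():
    """Four clade-C leaves on a hand-built guide tree; X and Y are
    sisters under internal node 2 (preorder numbering from the root)."""
    rng = np.random.default_rng(5)
    base = "".join(rng.choice(list("ACGT"), size=200))
    x = list(base)
    y = list(base)
    # X and Y differ at 4 fixed positions
    for pos, (bx, by) in zip((20, 60, 100, 140), [("A", "C")] * 4):
        x[pos] = bx
        y[pos] = by
    far1 = "".join("A" if b != "A" else "C" for b in base[:40]) + base[40:]
    far2 = "".join("G" if b != "G" else "T" for b in base[:40]) + base[40:]
    tree = TreeNode.read(["((X,Y),(Z,W));"])
    records = [RefRecord("X", "C", "".join(x)),
               RefRecord("Y", "C", "".join(y)),
               RefRecord("Z", "C", far1),
               RefRecord("W", "C", far2)]
    db = ReferenceDB(records, {"C": tree})
    # read takes two variant positions from X and two from Y
    read = list(base)
    read[20], read[60] = x[20], x[60]
    read[100], read[140] = y[100], y[140]
    return db, "".join(read)


def test_assign_subtype_tie_placed_at_lca():
    db, read = _lca_fixture()
    label = assign_subtype(read, "C", db)
    assert label == TaxonLabel("internal", "C", "C_i:2")


def test_guide_tree_preorder_numbering():
    db, _ = _lca_fixture()
    tree = db.guide_tree("C")
    names = [n.name for n in tree.preorder() if not n.is_tip()]
    assert names == ["1", "2", "3"]


# ---------------------------------------------------------------------------
# de novo clustering


def oracle_greedy_clusters(seqs_with_ids, identity):
    """Independent greedy clustering using a pure-python DP edit
    distance over the full pairwise matrix."""
    def dp_dist(a, b):
        prev = list(range(len(b) + 1))
        for i, ca in enumerate(a, 1):
            cur = [i]
            for j, cb in enumerate(b, 1):
                cur.append(min(prev[j - 1] + (ca != cb), prev[j] + 1,
                               cur[-1] + 1))
            prev = cur
        return prev[-1]

    groups = {}
    for rid, seq in seqs_with_ids:
        groups.setdefault(seq, []).append(rid)
    order = sorted(groups, key=lambda s: (-len(groups[s]), min(groups[s])))
    centroids = []
    out = {}
    for seq in order:
        target = None
        for ci, cen in enumerate(centroids):
            if 1 - dp_dist(seq, cen) / max(len(seq), len(cen)) >= identity:
                target = ci
                break
        if target is None:
            centroids.append(seq)
            target = len(centroids) - 1
        for rid in groups[seq]:
            out[rid] = target + 1
    return out


def test_cluster_identical_reads_single_cluster():
    reads = [read_of("ACGT" * 30, rid=f"r{i}") for i in range(10)]
    labels = cluster_denovo(reads, {r.read_id: "C" for r in reads})
    assert set(labels.values()) == {"C_d:1"}


def test_cluster_dissimilar_pair_two_clusters():
    a = "ACGT" * 30
    b = a[:60] + "TTTTGGGGCCCC" + a[72:]  # ~90% identical
    assert global_identity(a, b) < 0.97
    labels = cluster_denovo([read_of(a, rid="r1"), read_of(b, rid="r2")],
                            {"r1": "C", "r2": "C"})
    assert labels["r1"] != labels["r2"]


@pytest.mark.parametrize("seed", range(4))
def test_cluster_denovo_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list("ACGT"), size=120))
    reads = []
    for i in range(14):
        arr = list(base)
        n_mut = int(rng.integers(0, 10))
        for pos in rng.choice(len(base), size=n_mut, replace=False):
            arr[pos] = rng.choice([b for b in "ACGT" if b != arr[pos]])
        reads.append(read_of("".join(arr), rid=f"r{i:02d}"))
    labels = cluster_denovo(reads, {r.read_id: "C" for r in reads})
    oracle = oracle_greedy_clusters([(r.read_id, r.sequence) for r in reads],
                                    0.97)
    got = {rid: int(lab.split(":")[1]) for rid, lab in labels.items()}
    assert got == oracle


def test_cluster_numbering_by_founding_order():
    a, b = "ACGT" * 30, "TGCA" * 30
    reads = [read_of(a, rid="r1"), read_of(a, rid="r2"), read_of(b, rid="r3")]
    labels = cluster_denovo(reads, {r.read_id: "C" for r in reads})
    assert labels["r1"] == labels["r2"] == "C_d:1"  # most abundant founds 1
    assert labels["r3"] == "C_d:2"


# ---------------------------------------------------------------------------
# labels and count table


@pytest.mark.parametrize("name,kind,clade", [
    ("C3", "leaf", None),
    ("C_i:52", "internal", "C"),
    ("A_d:751", "denovo", "A"),
    ("unassigned", "unassigned", None),
])
def test_label_grammar_round_trip(name, kind, clade):
    label = parse_label(name)
    assert label.kind == kind
    assert label.clade == clade
    assert label.name == name  # serialization is the name itself


def test_bad_labels_rejected():
    with pytest.raises(ValueError):
        TaxonLabel("internal", "C", "C_x:1")
    with pytest.raises(ValueError):
        TaxonLabel("unassigned", "C", "unassigned")


def _meta(samples):
    return pd.DataFrame(
        {"pool": 300, "compartment": "water", "species": None},
        index=pd.Index(samples, name="sample_id"))


def test_build_count_table_merges_counts():
    leaf = TaxonLabel("leaf", "C", "C3")
    dn = TaxonLabel("denovo", "C", "C_d:1")
    table, qc = build_count_table(
        [("s1", leaf), ("s1", leaf), ("s2", dn)], _meta(["s1", "s2"]))
    assert table.counts.loc["s1", "C3"] == 2
    assert table.counts.loc["s2", "C_d:1"] == 1
    assert qc.loc["s1", "assigned"] == 2


def test_build_count_table_empty_assignments():
    table, qc = build_count_table([], _meta(["s1", "s2"]))
    assert list(table.samples) == ["s1", "s2"]
    assert table.taxa == []


def test_build_count_table_unknown_sample_raises():
    leaf = TaxonLabel("leaf", "C", "C3")
    with pytest.raises(ValueError, match="s9"):
        build_count_table([("s9", leaf)], _meta(["s1"]))


def test_read_conservation_and_clade_consistency(small_survey):
    """Assigned + unassigned totals equal input counts per sample, and
    each read's final clade matches its clade call."""
    reads = small_survey["reads"][:1500]
    db = small_survey["db"]
    assignments = taxonomy.classify_reads(reads, db)
    md = small_survey["table"].metadata
    table, qc = build_count_table(assignments, md)
    per_sample_in = pd.Series([r.sample_id for r in reads]).value_counts()
    for sample, n_in in per_sample_in.items():
        assert qc.loc[sample, "assigned"] + qc.loc[sample, "unassigned"] == n_in
    assert (table.counts.sum(axis=1) == qc["assigned"]).all()
    for a in assignments:
        if a.label.kind in ("internal", "denovo"):
            assert a.label.name.startswith(a.label.clade)
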