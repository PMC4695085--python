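"""Hierarchical taxonomy assignment for Symbiodinium ITS2 amplicons.

Each quality-controlled read is pushed through a three-tier classifier:

1. **Clade** (A, C, D, F, G): the read is scored against every reference
   of each clade; a clade is called only when the best E-value passes a
   hard cutoff *and* beats the next-best clade by a large ratio,
   otherwise the read is left unassigned.
2. **Subtype**: within the assigned clade, hits must pass an E-value
   cutoff, >97% identity, and >90% reference coverage. A unique best hit
   yields the reference (leaf) name; several equally good hits place the
   read at the lowest common ancestor of those leaves on the clade guide
   tree (label ``<clade>_i:<node>``); no qualifying hit marks the read
   "new".
3. **De novo OTU**: "new" reads are greedily clustered within their
   clade at 97% global identity in decreasing-abundance order (label
   ``<clade>_d:<cluster>``).

Counts of all labelled reads are merged into a samples x taxa table.
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, replace

import edlib
import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .alignment import (
    IUPAC_EQUALITIES,
    align_stats,
    edit_distance,
    global_identity,
    log10_evalue,
    revcomp,
)

logger = logging.getLogger(__name__)

CLADES = ("A", "C", "D", "F", "G")

_INTERNAL_RE = re.compile(r"^([A-Z])_i:(\d+)$")
_DENOVO_RE = re.compile(r"^([A-Z])_d:(\d+)$")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class AmpliconRead:
    """One demultiplexed sequencing read (optionally with qualities)."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...] | None = None
    sample_id: str = ""

    def __post_init__(self):
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RefRecord:
    name: str
    clade: str
    sequence: str


class ReferenceDB:
    """Clade-labelled ITS2 reference sequences plus per-clade guide trees.

    Guide-tree leaves must be reference names of that clade; internal
    nodes carry unique integer labels (assigned by preorder when the
    input tree leaves them unnamed).
    """

    def __init__(self, records: list[RefRecord],
                 guide_trees: dict[str, TreeNode] | None = None):
        if not records:
            raise ValueError("reference database is empty")
        names = [r.name for r in records]
        if len(set(names)) != len(names):
            raise ValueError("duplicate reference names in database")
        self.records = list(records)
        self.by_clade: dict[str, list[RefRecord]] = defaultdict(list)
        for r in self.records:
            self.by_clade[r.clade].append(r)
        self.total_length = sum(len(r.sequence) for r in self.records)
        self.guide_trees: dict[str, TreeNode] = {}
        if guide_trees:
            for clade, tree in guide_trees.items():
                leaves = {t.name for t in tree.tips()}
                expected = {r.name for r in self.by_clade.get(clade, [])}
                if not leaves <= expected:
                    raise ValueError(
                        f"guide tree for clade {clade} has leaves "
                        f"{sorted(leaves - expected)} not in the database"
                    )
                self.guide_trees[clade] = number_internal_nodes(tree)

    @property
    def clades(self) -> list[str]:
        return sorted(self.by_clade)

    def guide_tree(self, clade: str) -> TreeNode:
        """Guide tree for a clade, built by neighbor joining on pairwise
        alignment distances (midpoint-rooted) when none was supplied."""
        if clade not in self.guide_trees:
            self.guide_trees[clade] = build_guide_tree(self.by_clade[clade])
        return self.guide_trees[clade]


@dataclass(frozen=True)
class TaxonLabel:
    """A read's taxon: reference leaf, internal tree node, de novo OTU,
    transitional "new" (pre-clustering), or unassigned."""

    kind: str  # leaf | internal | denovo | new | unassigned
    clade: str | None
    name: str

    def __post_init__(self):
        if self.kind == "internal" and not _INTERNAL_RE.match(self.name):
            raise ValueError(f"bad internal-node label {self.name!r}")
        if self.kind == "denovo" and not _DENOVO_RE.match(self.name):
            raise ValueError(f"bad de novo label {self.name!r}")
        if self.kind == "unassigned" and self.clade is not None:
            raise ValueError("unassigned labels carry no clade")


def parse_label(name: str, clade_of_leaf: dict[str, str] | None = None) -> TaxonLabel:
    """Parse a serialized taxon name back into a TaxonLabel."""
    if name == "unassigned":
        return TaxonLabel("unassigned", None, name)
    m = _INTERNAL_RE.match(name)
    if m:
        return TaxonLabel("internal", m.group(1), name)
    m = _DENOVO_RE.match(name)
    if m:
        return TaxonLabel("denovo", m.group(1), name)
    clade = clade_of_leaf.get(name) if clade_of_leaf else None
    return TaxonLabel("leaf", clade, name)


@dataclass(frozen=True)
class SearchHit:
    reference_name: str
    clade: str
    bitscore: float
    e_value: float
    identity_fraction: float
    reference_coverage: float


@dataclass(frozen=True)
class CladeCall:
    clade: str | None
    e_value: float = math.inf
    log10_e: float = math.inf

    @property
    def assigned(self) -> bool:
        return self.clade is not None


# ---------------------------------------------------------------------------
# guide trees


def number_internal_nodes(tree: TreeNode) -> TreeNode:
    """Assign integer names 1.. to unnamed internal nodes, by preorder."""
    taken = {int(n.name) for n in tree.non_tips(include_self=True)
             if n.name is not None and str(n.name).isdigit()}
    nxt = 1
    for node in tree.preorder():
        if node.is_tip():
            continue
        if node.name is None or str(node.name) == "":
            while nxt in taken:
                nxt += 1
            node.name = str(nxt)
            taken.add(nxt)
    return tree


def build_guide_tree(records: list[RefRecord]) -> TreeNode:
    """Neighbor-joining guide tree over one clade's references,
    midpoint-rooted, internal nodes numbered by preorder."""
    if len(records) == 1:
        tree = TreeNode(name=None, children=[TreeNode(name=records[0].name)])
        return number_internal_nodes(tree)
    if len(records) == 2:
        tree = TreeNode(name=None,
                        children=[TreeNode(name=r.name) for r in records])
        return number_internal_nodes(tree)
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i].sequence, records[j].sequence
            d[i, j] = d[j, i] = edit_distance(a, b) / max(len(a), len(b))
    dm = DistanceMatrix(d, ids=[r.name for r in records])
    tree = nj(dm)
    try:
        tree = tree.root_at_midpoint()
    except Exception:  # degenerate (e.g. all-zero) distances
        pass
    return number_internal_nodes(tree)


# ---------------------------------------------------------------------------
# read quality control


def quality_trim(read: AmpliconRead, q_threshold: float = 25.0,
                 window: int = 10) -> AmpliconRead:
    """Trim the 3' end where the trailing running quality mean drops
    below ``q_threshold``.

    The read is truncated after the last position whose trailing window
    (that position and up to ``window - 1`` preceding bases) has mean
    quality >= the threshold; reads with no such position come back
    empty. Reads without qualities pass through unchanged.
    """
    if read.qualities is None:
        logger.warning("read %s has no qualities; quality trimming skipped",
                       read.read_id)
        return read
    q = np.asarray(read.qualities, dtype=float)
    if q.size == 0:
        return read
    csum = np.concatenate([[0.0], np.cumsum(q)])
    starts = np.maximum(np.arange(q.size) - window + 1, 0)
    means = (csum[np.arange(1, q.size + 1)] - csum[starts]) / (
        np.arange(q.size) - starts + 1)
    ok = np.nonzero(means >= q_threshold)[0]
    cut = int(ok[-1]) + 1 if ok.size else 0
    if cut == len(read.sequence):
        return read
    return replace(read, sequence=read.sequence[:cut],
                   qualities=tuple(read.qualities[:cut]))


def filter_homopolymer(read: AmpliconRead, max_run: int = 6) -> bool:
    """Keep the read unless any single-base run exceeds ``max_run``."""
    return re.search(r"(.)\1{%d,}" % max_run, read.sequence) is None


def trim_primers(read: AmpliconRead, forward_primer: str, reverse_primer: str,
                 max_errors: int = 3) -> AmpliconRead | None:
    """Locate and remove primer spans (IUPAC-aware, <= ``max_errors``
    edits each); a read without a forward-primer match is rejected
    (None); a missing reverse match trims the forward side only.

    The reverse primer is searched as its reverse complement, as it
    appears on the read strand. Each primer's best semi-global match is
    used; the insert between the two spans is returned.
    """
    seq = read.sequence
    fwd = edlib.align(forward_primer.upper(), seq, mode="HW", task="locations",
                      k=max_errors, additionalEqualities=IUPAC_EQUALITIES)
    if fwd["editDistance"] == -1:
        return None
    fstart, fend = fwd["locations"][0]
    insert_start = fend + 1
    rest = seq[insert_start:]
    insert_end = len(seq)
    rev = edlib.align(revcomp(reverse_primer), rest, mode="HW",
                      task="locations", k=max_errors,
                      additionalEqualities=IUPAC_EQUALITIES)
    if rev["editDistance"] != -1:
        insert_end = insert_start + rev["locations"][0][0]
    quals = (read.qualities[insert_start:insert_end]
             if read.qualities is not None else None)
    return replace(read, sequence=seq[insert_start:insert_end], qualities=quals)


# ---------------------------------------------------------------------------
# clade assignment


def _clade_log_evalues(seq: str, db: ReferenceDB,
                       ratio_cutoff: float | None = None) -> dict[str, float]:
    """Best log10 E-value per clade for one read sequence.

    Scores come from banded end-to-end edit distance against every
    reference: score = max(len) - 3*d under the +1/-2 scheme (each edit
    both forfeits a match and incurs the penalty). When a
    ``ratio_cutoff`` is given, alignments are abandoned once a
    reference falls so far behind the best hit that its clade could not
    affect the E-value ratio decision; such clades report +inf.
    """
    from .alignment import karlin_lambda

    margin = None
    if ratio_cutoff is not None:
        score_gap = math.log(1.0 / ratio_cutoff) / karlin_lambda()
        margin = math.ceil(score_gap / 3.0) + 2
    out: dict[str, float] = {}
    best_d = math.inf
    for clade, refs in db.by_clade.items():
        best = math.inf
        for ref in refs:
            k = -1
            if margin is not None and math.isfinite(best_d):
                k = int(best_d) + margin
            d = edlib.align(seq, ref.sequence, mode="NW", task="distance",
                            k=k,
                            additionalEqualities=IUPAC_EQUALITIES)["editDistance"]
            if d == -1:
                continue
            best_d = min(best_d, d)
            score = max(len(seq), len(ref.sequence)) - 3 * d
            le = log10_evalue(score, len(seq), db.total_length)
            if le < best:
                best = le
        out[clade] = best
    return out


def assign_clade(read: AmpliconRead | str, db: ReferenceDB,
                 e_cutoff: float = 1e-20,
                 ratio_cutoff: float = 1e-5) -> CladeCall:
    """Call the read's clade, or leave it unassigned.

    A clade is assigned iff its best E-value is <= ``e_cutoff`` and is at
    least ``1/ratio_cutoff``-fold smaller than the best E-value of any
    other clade (a database with references from a single clade counts
    as satisfying the ratio).
    """
    seq = read if isinstance(read, str) else read.sequence
    if not seq:
        return CladeCall(None)
    log_e = _clade_log_evalues(seq, db, ratio_cutoff=ratio_cutoff)
    ranked = sorted(log_e.items(), key=lambda kv: kv[1])
    best_clade, best = ranked[0]
    if best > math.log10(e_cutoff):
        return CladeCall(None, log10_e=best)
    if len(ranked) > 1:
        second = ranked[1][1]
        if best - second > math.log10(ratio_cutoff):
            return CladeCall(None, log10_e=best)
    return CladeCall(best_clade, e_value=10.0 ** max(best, -300.0), log10_e=best)


# ---------------------------------------------------------------------------
# subtype assignment


def search_clade(seq: str, clade: str, db: ReferenceDB) -> list[SearchHit]:
    """Alignment hits of a read against one clade's references."""
    hits = []
    for ref in db.by_clade[clade]:
        st = align_stats(seq, ref.sequence)
        if st is None:
            continue
        le = log10_evalue(st.score, len(seq), db.total_length)
        hits.append(SearchHit(
            reference_name=ref.name,
            clade=clade,
            bitscore=float(st.score),
            e_value=10.0 ** max(min(le, 300.0), -300.0),
            identity_fraction=st.identity,
            reference_coverage=st.ref_coverage,
        ))
    return hits


def assign_subtype(read: AmpliconRead | str, clade: str, db: ReferenceDB,
                   e_cutoff: float = 1e-20, min_identity: float = 0.97,
                   min_ref_coverage: float = 0.90) -> TaxonLabel:
    """Assign a clade-classified read to a leaf, an internal LCA node,
    or mark it "new" for de novo clustering.

    Hits qualify when E <= ``e_cutoff``, identity > ``min_identity`` and
    reference coverage > ``min_ref_coverage``. Top hits are tied when
    their scores are equal (within 1e-9 relative tolerance) and their
    identities agree to 4 decimal places; ties are placed at the leaves'
    lowest common ancestor on the clade guide tree.
    """
    if clade not in db.by_clade:
        raise ValueError(f"clade {clade!r} has no references in the database")
    seq = read if isinstance(read, str) else read.sequence
    # banded prescreen: a reference whose end-to-end distance exceeds the
    # identity budget plus the length difference cannot qualify
    candidates = []
    for ref in db.by_clade[clade]:
        max_len = max(len(seq), len(ref.sequence))
        k = (math.ceil((1.0 - min_identity) * max_len)
             + abs(len(seq) - len(ref.sequence)) + 3)
        d = edlib.align(seq, ref.sequence, mode="NW", task="distance", k=k,
                        additionalEqualities=IUPAC_EQUALITIES)["editDistance"]
        if d != -1:
            candidates.append(ref)
    hits = []
    for ref in candidates:
        st = align_stats(seq, ref.sequence)
        if st is None:
            continue
        le = log10_evalue(st.score, len(seq), db.total_length)
        h = SearchHit(ref.name, clade, float(st.score),
                      10.0 ** max(min(le, 300.0), -300.0),
                      st.identity, st.ref_coverage)
        if (h.e_value <= e_cutoff and h.identity_fraction > min_identity
                and h.reference_coverage > min_ref_coverage):
            hits.append(h)
    if not hits:
        return TaxonLabel("new", clade, "new")
    top = max(hits, key=lambda h: (h.bitscore, h.identity_fraction))
    tied = [h for h in hits
            if math.isclose(h.bitscore, top.bitscore, rel_tol=1e-9, abs_tol=1e-9)
            and round(h.identity_fraction, 4) == round(top.identity_fraction, 4)]
    if len(tied) == 1:
        return TaxonLabel("leaf", clade, top.reference_name)
    tree = db.guide_tree(clade)
    node = tree.lca([h.reference_name for h in tied])
    if node.is_tip():  # single-leaf degenerate tree
        return TaxonLabel("leaf", clade, node.name)
    return TaxonLabel("internal", clade, f"{clade}_i:{node.name}")


# ---------------------------------------------------------------------------
# de novo clustering


def cluster_denovo(reads: list[AmpliconRead], clades: dict[str, str],
                   identity: float = 0.97) -> dict[str, str]:
    """Greedy centroid clustering of "new" reads within each clade.

    Unique sequences are processed in decreasing abundance (ties broken
    by the lexicographically smallest read id carrying the sequence); a
    sequence joins the first centroid, in founding order, with global
    identity >= ``identity``, otherwise it founds the next cluster.
    Returns read_id -> "<clade>_d:<cluster>" with clusters numbered from
    1 per clade in founding order.
    """
    by_clade: dict[str, dict[str, list[str]]] = defaultdict(lambda: defaultdict(list))
    for read in reads:
        clade = clades[read.read_id]
        by_clade[clade][read.sequence].append(read.read_id)
    labels: dict[str, str] = {}
    for clade in sorted(by_clade):
        seq_reads = by_clade[clade]
        order = sorted(seq_reads,
                       key=lambda s: (-len(seq_reads[s]), min(seq_reads[s])))
        centroids: list[str] = []
        for seq in order:
            assigned = None
            max_d_allowed = None
            for idx, cen in enumerate(centroids):
                max_len = max(len(seq), len(cen))
                k = int(math.floor((1.0 - identity) * max_len))
                d = edit_distance(seq, cen, k=k)
                if d != -1 and 1.0 - d / max_len >= identity:
                    assigned = idx
                    break
            if assigned is None:
                centroids.append(seq)
                assigned = len(centroids) - 1
            label = f"{clade}_d:{assigned + 1}"
            for rid in seq_reads[seq]:
                labels[rid] = label
    return labels


# ---------------------------------------------------------------------------
# driver and count table


@dataclass
class Assignment:
    read_id: str
    sample_id: str
    label: TaxonLabel
    e_value: float = math.nan
    identity: float = math.nan


def classify_reads(reads: list[AmpliconRead], db: ReferenceDB,
                   e_cutoff: float = 1e-20, ratio_cutoff: float = 1e-5,
                   min_identity: float = 0.97, min_ref_coverage: float = 0.90,
                   cluster_identity: float = 0.97) -> list[Assignment]:
    """Run the full hierarchical classifier over a batch of reads.

    Identical sequences are classified once and the result reused, which
    makes error-free or low-error read sets much cheaper.
    """
    cache: dict[str, tuple[CladeCall, TaxonLabel | None]] = {}
    assignments: list[Assignment] = []
    new_reads: list[AmpliconRead] = []
    new_clades: dict[str, str] = {}
    pending: dict[str, list[int]] = defaultdict(list)

    for read in reads:
        if read.sequence not in cache:
            call = assign_clade(read, db, e_cutoff, ratio_cutoff)
            label = None
            if call.assigned:
                label = assign_subtype(read, call.clade, db, e_cutoff,
                                       min_identity, min_ref_coverage)
            cache[read.sequence] = (call, label)
        call, label = cache[read.sequence]
        if not call.assigned:
            assignments.append(Assignment(read.read_id, read.sample_id,
                                          TaxonLabel("unassigned", None,
                                                     "unassigned")))
        elif label is not None and label.kind == "new":
            idx = len(assignments)
            assignments.append(Assignment(read.read_id, read.sample_id, label,
                                          e_value=call.e_value))
            new_reads.append(read)
            new_clades[read.read_id] = call.clade
            pending[read.read_id].append(idx)
        else:
            assignments.append(Assignment(read.read_id, read.sample_id, label,
                                          e_value=call.e_value))

    if new_reads:
        denovo = cluster_denovo(new_reads, new_clades, cluster_identity)
        for rid, name in denovo.items():
            for idx in pending[rid]:
                assignments[idx].label = parse_label(name)
    return assignments


def build_count_table(assignments: list, metadata: pd.DataFrame):
    """Merge per-read taxon assignments into a samples x taxa count
    table joined to sample metadata; unassigned reads are excluded from
    the table but tallied in the returned QC report.

    Accepts ``Assignment`` objects or bare ``(sample_id, TaxonLabel)``
    pairs. Returns ``(CountTable, qc_report)`` where the QC report is a
    per-sample DataFrame of assigned/unassigned read counts.
    """
    from .table import CountTable

    pairs = []
    for a in assignments:
        if isinstance(a, tuple):
            pairs.append(a)
        else:
            pairs.append((a.sample_id, a.label))
    missing = sorted({s for s, _ in pairs} - set(metadata.index))
    if missing:
        raise ValueError(f"samples absent from metadata: {missing}")

    counts: dict[tuple[str, str], int] = Counter()
    qc: dict[str, Counter] = defaultdict(Counter)
    for sample_id, label in pairs:
        if label.kind == "unassigned":
            qc[sample_id]["unassigned"] += 1
        else:
            counts[(sample_id, label.name)] += 1
            qc[sample_id]["assigned"] += 1
    taxa = sorted({t for _, t in counts})
    samples = list(metadata.index)
    mat = pd.DataFrame(0, index=samples, columns=taxa, dtype=int)
    for (s, t), c in counts.items():
        mat.loc[s, t] = c
    qc_report = pd.DataFrame(
        [{"sample_id": s,
          "assigned": qc[s].get("assigned", 0),
          "unassigned": qc[s].get("unassigned", 0)} for s in samples]
    ).set_index("sample_id")
    return CountTable(mat, metadata), qc_report
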