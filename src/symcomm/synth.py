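"""Truth-known synthetic data with the structure the analysis assumes.

Three generators cover the whole chain:

- :func:`make_reference_db` evolves an ITS2-like root sequence into five
  clades (A, C, D, F, G) of reference subtypes under a substitution
  process, together with guide trees and optional "novel" taxa that are
  deliberately below the subtype identity threshold (they exercise the
  de novo clustering path).
- :func:`simulate_community` draws per-sample taxon proportions for a
  two-pool, three-compartment sampling design with planted between-pool
  fold-changes, within-pool spatial gradients, sample-to-sample
  compositional noise, and log-normal library sizes, then draws
  multinomial counts.
- :func:`simulate_reads` emits one read per count by copying the source
  sequence with independent substitution errors (optionally with primer
  flanks or planted homopolymer runs).

Every generator is deterministic given its seed, and every random
quantity is recorded in a truth object so downstream modules can be
scored without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .alignment import global_identity, revcomp
from .table import CountTable
from .taxonomy import AmpliconRead, RefRecord, ReferenceDB, number_internal_nodes

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# ITS2 amplification primers (forward 'its-dino', reverse 'its2rev2')
FORWARD_PRIMER = "GTGAATTGCAGAACTCCGTG"
REVERSE_PRIMER = "CCTCCGCTTACTTATATGCTT"

DEFAULT_LENGTH = 330
DEPTH_GEOMETRIC_MEAN = 1011.0
DEPTH_GEOMETRIC_SD = 3.8
DEPTH_MIN = 33

CORAL_SPECIES = (
    "Psammocora contigua", "Porites mound", "Porites annae",
    "Pocillopora damicornis", "Pavona venosa", "Leptoria phrygia",
    "Goniastrea retiformis", "Favia matthaii", "Acropora pagoensis",
    "Acropora austera",
)


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


def _array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _mutate(arr: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base independently with probability p (new base
    drawn uniformly from the three alternatives)."""
    out = arr.copy()
    hit = np.nonzero(rng.random(arr.size) < p)[0]
    if hit.size:
        cur = np.searchsorted(BASES, out[hit])
        shift = rng.integers(1, 4, size=hit.size)
        out[hit] = BASES[(cur + shift) % 4]
    return out


def _break_homopolymers(arr: np.ndarray, rng: np.random.Generator,
                        max_run: int = 6) -> np.ndarray:
    """Substitute within any homopolymer run longer than ``max_run`` so
    reference sequences survive the QC homopolymer filter; only reads
    with deliberately planted runs should be discarded by it."""
    out = arr.copy()
    run_start = 0
    for i in range(1, len(out) + 1):
        if i == len(out) or out[i] != out[run_start]:
            length = i - run_start
            if length > max_run:
                for j in range(run_start + max_run, i, max_run + 1):
                    cur = int(np.searchsorted(BASES, out[j]))
                    out[j] = BASES[(cur + int(rng.integers(1, 4))) % 4]
            run_start = i
    return out


# ---------------------------------------------------------------------------
# reference database


@dataclass
class ReferenceTruth:
    """Generating process of a synthetic reference database."""

    root_sequence: str
    clade_ancestors: dict[str, str]
    trees: dict[str, TreeNode]
    novel: dict[str, tuple[str, str]]  # name -> (clade, sequence)
    within_clade_divergence: float
    between_clade_divergence: float
    seed: int

    def clade_of(self, taxon: str) -> str | None:
        if taxon in self.novel:
            return self.novel[taxon][0]
        return taxon[0] if taxon[:1] in "ACDFG" else None


def _evolve_clade(ancestor: np.ndarray, names: list[str], levels: int,
                  p_level: float, rng: np.random.Generator):
    """Recursive balanced splitting: every leaf accumulates exactly
    ``levels`` mutation rounds of rate ``p_level`` below the ancestor,
    with shared rounds following the split topology."""
    seqs: dict[str, np.ndarray] = {}

    def recurse(seq: np.ndarray, block: list[str], lev: int) -> TreeNode:
        if len(block) == 1:
            leaf_seq = seq
            for _ in range(lev):
                leaf_seq = _mutate(leaf_seq, p_level, rng)
            seqs[block[0]] = leaf_seq
            return TreeNode(name=block[0], length=max(lev, 1) * p_level)
        half = len(block) // 2
        order = list(rng.permutation(len(block)))
        left = [block[i] for i in order[:half]]
        right = [block[i] for i in order[half:]]
        children = []
        for part in (left, right):
            child_seq = _mutate(seq, p_level, rng)
            children.append(recurse(child_seq, part, lev - 1))
        node = TreeNode(children=children, length=p_level)
        return node

    tree = recurse(ancestor, names, levels)
    if tree.is_tip():  # single reference in the clade
        tree = TreeNode(children=[tree])
    return tree, seqs


def make_reference_db(n_per_clade: int = 6,
                      within_clade_divergence: float = 0.05,
                      between_clade_divergence: float = 0.25,
                      length: int = DEFAULT_LENGTH,
                      n_novel_per_clade: int = 1,
                      seed: int = 0) -> tuple[ReferenceDB, ReferenceTruth]:
    """Simulate a clade-labelled ITS2 reference database.

    A random root sequence is evolved into one ancestor per clade at
    ``between_clade_divergence``, and each ancestor into
    ``n_per_clade`` reference leaves whose expected divergence from the
    ancestor is ``within_clade_divergence``. Guide trees follow the
    generating topology. Novel taxa (``<clade>x<i>``) are evolved past
    the 97% identity radius of every reference and returned only in the
    truth object.
    """
    if not 0 <= within_clade_divergence < 1 or not 0 < between_clade_divergence < 1:
        raise ValueError("divergences must lie in (0, 1)")
    if between_clade_divergence <= within_clade_divergence:
        raise ValueError("between-clade divergence must exceed within-clade "
                         "divergence, otherwise clades are not separable")
    rng = np.random.default_rng(seed)
    root = BASES[rng.integers(0, 4, size=length)]
    records: list[RefRecord] = []
    trees: dict[str, TreeNode] = {}
    ancestors: dict[str, str] = {}
    novel: dict[str, tuple[str, str]] = {}
    for clade in ("A", "C", "D", "F", "G"):
        anc = _mutate(root, between_clade_divergence, rng)
        ancestors[clade] = _array_to_seq(anc)
        names = [f"{clade}{i + 1}" for i in range(n_per_clade)]
        levels = max(math.ceil(math.log2(max(n_per_clade, 2))), 1)
        p_level = within_clade_divergence / levels
        tree, seqs = _evolve_clade(anc, names, levels, p_level, rng)
        trees[clade] = number_internal_nodes(tree)
        for name in names:
            seqs[name] = _break_homopolymers(seqs[name], rng)
            records.append(RefRecord(name, clade, _array_to_seq(seqs[name])))
        ref_seqs = [_array_to_seq(seqs[n]) for n in names]
        for j in range(n_novel_per_clade):
            rate = max(0.06, 1.5 * within_clade_divergence)
            base = seqs[names[int(rng.integers(0, len(names)))]]
            for _ in range(25):
                cand = _array_to_seq(_break_homopolymers(
                    _mutate(base, rate, rng), rng))
                if all(global_identity(cand, r) < 0.965 for r in ref_seqs):
                    break
                rate *= 1.25
            novel[f"{clade}x{j + 1}"] = (clade, cand)
    db = ReferenceDB(records, {c: t.copy() for c, t in trees.items()})
    truth = ReferenceTruth(
        root_sequence=_array_to_seq(root),
        clade_ancestors=ancestors,
        trees=trees,
        novel=novel,
        within_clade_divergence=within_clade_divergence,
        between_clade_divergence=between_clade_divergence,
        seed=seed,
    )
    return db, truth


# ---------------------------------------------------------------------------
# community design


@dataclass
class SampleGroup:
    """One stratum of the sampling design."""

    compartment: str
    n_per_pool: int
    species: str | None = None
    concentration: float = 40.0  # Dirichlet precision: lower = more variable
    emphasis: int = 0  # rotates which subtype dominates within each clade


@dataclass
class Scenario:
    """Everything needed to draw a synthetic survey.

    ``clade_mixtures`` maps a group key (compartment or species name) to
    clade proportions; ``fold_changes`` maps a group key to taxon- or
    clade-level multiplicative effects applied in pool 300;
    ``gradients`` maps a compartment to per-meter log-abundance slopes
    along the offshore axis (optionally restricted to one pool via key
    ``(compartment, pool)``).
    """

    groups: list[SampleGroup]
    clade_mixtures: dict[str, dict[str, float]]
    fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)
    gradients: dict = field(default_factory=dict)
    depth_geometric_mean: float = DEPTH_GEOMETRIC_MEAN
    depth_geometric_sd: float = DEPTH_GEOMETRIC_SD
    depth_min: int = DEPTH_MIN
    novel_fraction: float = 0.06
    error_rate: float = 0.002
    pools: tuple[int, int] = (300, 400)


def default_scenario() -> Scenario:
    """The shipped study design: two pools, water n=29/pool, sediment
    n=30/pool, ten coral species n=5/pool each, with clade mixtures per
    compartment, between-pool fold-changes concentrated in water,
    sediment, Pavona venosa (including a hundredfold clade D effect) and
    Psammocora contigua, and inshore-offshore gradients of clade A in
    water (both pools) and sediment (pool 400 only)."""
    groups = [
        SampleGroup("water", 29, concentration=25.0),
        SampleGroup("sediment", 30, concentration=8.0),
    ]
    coral_conc = {
        "Porites mound": 300.0, "Porites annae": 300.0,
        "Pavona venosa": 7.0, "Pocillopora damicornis": 5.0,
        "Acropora austera": 6.0, "Acropora pagoensis": 6.0,
        "Goniastrea retiformis": 12.0, "Favia matthaii": 12.0,
        "Leptoria phrygia": 18.0, "Psammocora contigua": 18.0,
    }
    coral_emphasis = {
        "Porites mound": 3, "Porites annae": 3, "Pavona venosa": 2,
        "Pocillopora damicornis": 1, "Acropora austera": 1,
        "Acropora pagoensis": 4, "Goniastrea retiformis": 0,
        "Favia matthaii": 5, "Leptoria phrygia": 0,
        "Psammocora contigua": 2,
    }
    for sp in CORAL_SPECIES:
        groups.append(SampleGroup("coral", 5, species=sp,
                                  concentration=coral_conc[sp],
                                  emphasis=coral_emphasis[sp]))
    mixtures = {
        "water": {"A": 0.28, "C": 0.58, "D": 0.06, "F": 0.05, "G": 0.03},
        "sediment": {"A": 0.22, "C": 0.45, "D": 0.22, "F": 0.07, "G": 0.04},
        "Psammocora contigua": {"C": 0.97, "A": 0.03},
        "Porites mound": {"C": 1.0},
        "Porites annae": {"C": 1.0},
        "Pocillopora damicornis": {"C": 0.55, "D": 0.42, "A": 0.03},
        # clade D rare at baseline so the planted hundredfold increase
        # takes it from background to dominance in pool 300
        "Pavona venosa": {"C": 0.945, "D": 0.005, "A": 0.05},
        "Leptoria phrygia": {"C": 0.90, "A": 0.05, "D": 0.05},
        "Goniastrea retiformis": {"C": 0.88, "A": 0.06, "D": 0.06},
        "Favia matthaii": {"C": 0.90, "A": 0.05, "D": 0.05},
        "Acropora pagoensis": {"C": 0.65, "D": 0.30, "A": 0.05},
        "Acropora austera": {"C": 0.65, "D": 0.30, "A": 0.05},
    }
    folds = {
        "water": {"D": 4.0, "C1": 3.0, "C2": 0.25, "A1": 2.0, "A2": 0.4},
        "sediment": {"D": 0.1, "A1": 3.0, "C3": 3.0, "C2": 0.3, "F1": 2.0},
        "Pavona venosa": {"D": 100.0, "C2": 0.25, "A1": 4.0},
        "Psammocora contigua": {"C1": 2.0, "C2": 0.5},
    }
    gradients = {
        "water": {"A": -0.046},            # clade A declines offshore
        ("sediment", 400): {"A": 0.046},   # clade A increases offshore
    }
    return Scenario(groups=groups, clade_mixtures=mixtures,
                    fold_changes=folds, gradients=gradients)


@dataclass
class CommunityTruth:
    """True per-sample composition and design of a simulated survey."""

    proportions: pd.DataFrame  # samples x taxa, sums to 1
    positions: pd.DataFrame  # local meters within pool: x (alongshore), y (offshore)
    scenario: Scenario
    seed: int


# anchor GPS coordinates (decimal degrees) for the two pools
POOL_ANCHORS = {300: (-14.1853, -169.6684), 400: (-14.1841, -169.6601)}


def _positions_for(group: SampleGroup, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Local (x alongshore, y offshore) meters for one pool's samples."""
    if group.compartment == "water":
        # three transects parallel to shore (1 m sample spacing along
        # shore) at increasing distance from shore across the pool
        per = math.ceil(n / 3)
        pos = [(float(i % per), 5.0 + 15.0 * (i // per)) for i in range(n)]
        return np.asarray(pos)
    if group.compartment == "sediment":
        return np.column_stack([rng.uniform(0, 60, n), rng.uniform(2, 40, n)])
    return np.column_stack([rng.uniform(0, 50, n), rng.uniform(1, 20, n)])


def _latlon_from_local(pool: int, xy: np.ndarray) -> np.ndarray:
    lat0, lon0 = POOL_ANCHORS[pool]
    r = 6_371_008.8
    lat = lat0 + np.degrees(xy[:, 1] / r)
    lon = lon0 + np.degrees(xy[:, 0] / (r * math.cos(math.radians(lat0))))
    return np.column_stack([lat, lon])


def _taxon_mixture(clade_mixture: dict[str, float], taxa_by_clade: dict,
                   novel_fraction: float, emphasis: int = 0) -> pd.Series:
    """Spread clade-level proportions across that clade's taxa with
    geometrically decaying weights; divert ``novel_fraction`` of each
    clade's mass to its novel taxa.

    ``emphasis`` rotates the weights so that different groups (e.g.
    coral species) are dominated by different subtypes of the same
    clade, as observed between host species on real reefs."""
    out = {}
    for clade, mass in clade_mixture.items():
        refs, novels = taxa_by_clade[clade]
        w = np.array([0.5 ** i for i in range(len(refs))])
        w = np.roll(w, emphasis % max(len(refs), 1))
        w = w / w.sum() * (1 - (novel_fraction if novels else 0.0))
        for name, wi in zip(refs, w):
            out[name] = mass * wi
        for name in novels:
            out[name] = mass * novel_fraction / len(novels)
    s = pd.Series(out)
    return s / s.sum()


def _fold_vector(taxa: pd.Index, folds: dict[str, float],
                 clade_of) -> np.ndarray:
    """Per-taxon multiplicative effects: keys may be taxon names or
    clade letters (applying to every taxon of the clade)."""
    f = np.ones(len(taxa))
    for i, t in enumerate(taxa):
        clade = clade_of(t)
        if t in folds:
            f[i] = folds[t]
        elif clade in folds:
            f[i] = folds[clade]
    return f


def simulate_community(scenario: Scenario, db: ReferenceDB,
                       truth_db: ReferenceTruth,
                       seed: int = 0) -> tuple[CountTable, CommunityTruth]:
    """Draw a full survey: metadata, true compositions, and counts.

    Per sample, the true proportions are the group's base taxon mixture
    times the pool's planted fold-changes times the spatial-gradient
    factor exp(slope * (y - y_mean)), renormalized, then jittered with a
    Dirichlet draw at the group's concentration. Library size is
    log-normal (geometric mean/sd from the scenario, floored by redraw
    at ``depth_min``) and counts are multinomial.
    """
    rng = np.random.default_rng(seed)
    taxa_by_clade = {}
    for clade in db.clades:
        refs = [r.name for r in db.by_clade[clade]]
        novels = [n for n, (c, _) in truth_db.novel.items() if c == clade]
        taxa_by_clade[clade] = (refs, novels)
    all_taxa: list[str] = []
    for clade in sorted(taxa_by_clade):
        refs, novels = taxa_by_clade[clade]
        all_taxa.extend(refs)
        all_taxa.extend(novels)
    taxa = pd.Index(all_taxa)

    ln_gm = math.log(scenario.depth_geometric_mean)
    ln_gsd = math.log(scenario.depth_geometric_sd)

    rows_counts, rows_meta, rows_prop, rows_pos = [], [], [], []
    sample_ids = []
    abbrev = {sp: "".join(w[0] for w in sp.split()).upper()
              for sp in CORAL_SPECIES}
    for group in scenario.groups:
        key = group.species or group.compartment
        base = _taxon_mixture(scenario.clade_mixtures[key], taxa_by_clade,
                              scenario.novel_fraction,
                              group.emphasis).reindex(taxa, fill_value=0.0)
        folds = _fold_vector(taxa, scenario.fold_changes.get(key, {}),
                             truth_db.clade_of)
        for pool in scenario.pools:
            xy = _positions_for(group, group.n_per_pool, rng)
            latlon = _latlon_from_local(pool, xy)
            grads = dict(scenario.gradients.get(group.compartment, {}))
            grads.update(scenario.gradients.get((group.compartment, pool), {}))
            slope = np.zeros(len(taxa))
            for i, t in enumerate(taxa):
                clade = truth_db.clade_of(t)
                if t in grads:
                    slope[i] = grads[t]
                elif clade in grads:
                    slope[i] = grads[clade]
            y_center = xy[:, 1].mean()
            for i in range(group.n_per_pool):
                p = base.to_numpy().copy()
                if pool == 300:
                    p = p * folds
                p = p * np.exp(slope * (xy[i, 1] - y_center))
                p = p / p.sum()
                alive = p > 0
                jitter = np.zeros(len(taxa))
                jitter[alive] = rng.dirichlet(p[alive] * group.concentration)
                depth = 0
                while depth < scenario.depth_min:
                    depth = int(round(float(
                        rng.lognormal(mean=ln_gm, sigma=ln_gsd))))
                counts = rng.multinomial(depth, jitter)
                tag = (f"W{pool}" if group.compartment == "water" else
                       f"S{pool}" if group.compartment == "sediment" else
                       f"{abbrev[group.species]}{pool}")
                sid = f"{tag}-{i + 1:02d}"
                sample_ids.append(sid)
                rows_counts.append(counts)
                rows_prop.append(jitter)
                rows_pos.append(xy[i])
                rows_meta.append({
                    "sample_id": sid, "pool": pool,
                    "compartment": group.compartment,
                    "species": group.species,
                    "latitude": latlon[i, 0], "longitude": latlon[i, 1],
                    "depth": float(rng.uniform(0.3, 2.0)),
                })

    counts = pd.DataFrame(rows_counts, index=sample_ids, columns=taxa)
    metadata = pd.DataFrame(rows_meta).set_index("sample_id")
    table = CountTable(counts, metadata)
    truth = CommunityTruth(
        proportions=pd.DataFrame(rows_prop, index=sample_ids, columns=taxa),
        positions=pd.DataFrame(rows_pos, index=sample_ids, columns=["x", "y"]),
        scenario=scenario,
        seed=seed,
    )
    return table, truth


# ---------------------------------------------------------------------------
# reads


def simulate_reads(table: CountTable, db: ReferenceDB,
                   truth_db: ReferenceTruth, error_rate: float = 0.002,
                   seed: int = 0, attach_primers: bool = False,
                   homopolymer_fraction: float = 0.0
                   ) -> tuple[list[AmpliconRead], pd.DataFrame]:
    """Emit ``count[s, t]`` reads per cell by copying the taxon's source
    sequence with independent substitution errors at ``error_rate``.

    Optionally wraps each read in the amplification primers (forward +
    insert + reverse complement of the reverse primer) and/or plants a
    disqualifying 7-base homopolymer run into a fraction of reads.
    Returns the reads and a truth frame (read_id, sample_id, taxon,
    clade). Raises for taxa with no source sequence.
    """
    rng = np.random.default_rng(seed)
    sources: dict[str, tuple[str, str]] = {}
    for rec in db.records:
        sources[rec.name] = (rec.clade, rec.sequence)
    sources.update(truth_db.novel)
    missing = [t for t in table.taxa if t not in sources]
    if missing:
        raise ValueError(f"taxa with no source sequence: {missing}")

    reads: list[AmpliconRead] = []
    truth_rows = []
    serial = 0
    counts = table.counts
    for taxon in table.taxa:
        col = counts[taxon]
        total = int(col.sum())
        if total == 0:
            continue
        clade, seq = sources[taxon]
        arr = _seq_to_array(seq)
        block = np.tile(arr, (total, 1))
        if error_rate > 0:
            mask = rng.random(block.shape) < error_rate
            if mask.any():
                idx = np.nonzero(mask)
                cur = np.searchsorted(BASES, block[idx])
                shift = rng.integers(1, 4, size=idx[0].size)
                block[idx] = BASES[(cur + shift) % 4]
        row = 0
        for sample_id, c in col.items():
            for _ in range(int(c)):
                s = _array_to_seq(block[row])
                row += 1
                if homopolymer_fraction and rng.random() < homopolymer_fraction:
                    pos = int(rng.integers(0, len(s)))
                    s = s[:pos] + s[pos:pos + 1] * 7 + s[pos + 1:]
                if attach_primers:
                    s = FORWARD_PRIMER + s + revcomp(REVERSE_PRIMER)
                rid = f"r{serial:07d}"
                serial += 1
                reads.append(AmpliconRead(rid, s, sample_id=sample_id))
                truth_rows.append((rid, sample_id, taxon, clade))
    truth = pd.DataFrame(truth_rows,
                         columns=["read_id", "sample_id", "taxon", "clade"])
    return reads, truth.set_index("read_id")


def draw_depths(n: int, geometric_mean: float = DEPTH_GEOMETRIC_MEAN,
                geometric_sd: float = DEPTH_GEOMETRIC_SD,
                minimum: int = DEPTH_MIN, seed: int = 0) -> np.ndarray:
    """Log-normal library sizes (redrawn below ``minimum``)."""
    rng = np.random.default_rng(seed)
    out = np.empty(n, dtype=int)
    for i in range(n):
        d = 0
        while d < minimum:
            d = int(round(float(rng.lognormal(
                mean=math.log(geometric_mean), sigma=math.log(geometric_sd)))))
        out[i] = d
    return out
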