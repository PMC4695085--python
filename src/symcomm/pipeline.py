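"""End-to-end orchestration: simulate (or load) reads, classify, and run
the full statistical chain, writing every stage's outputs to a run
directory together with the resolved configuration and its hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community, diffabund, io, spatial, synth, taxonomy
from .table import CountTable

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds, seeds, and MCMC controls for one run."""

    seed: int = 0
    # synthetic inputs (used when no reads/db paths are given)
    n_per_clade: int = 6
    within_clade_divergence: float = 0.05
    between_clade_divergence: float = 0.25
    error_rate: float = 0.002
    scale: float = 1.0  # shrinks group sizes & depth for quick runs
    # taxonomy thresholds
    e_cutoff: float = 1e-20
    ratio_cutoff: float = 1e-5
    min_identity: float = 0.97
    min_ref_coverage: float = 0.90
    cluster_identity: float = 0.97
    q_threshold: float = 25.0
    window: int = 10
    max_primer_errors: int = 3
    # statistics
    n_permutations: int = 9999
    n_permutations_mantel: int = 999
    min_fraction: float = 0.001
    fdr_q: float = 0.1
    alpha: float = 0.05
    force_diffabund: bool = False
    mcmc_iterations: int = 15_000
    mcmc_burn_in: int = 5_000
    mcmc_thin: int = 10

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _scaled_scenario(config: RunConfig) -> synth.Scenario:
    scenario = synth.default_scenario()
    scenario.error_rate = config.error_rate
    if config.scale != 1.0:
        for g in scenario.groups:
            g.n_per_pool = max(3, int(round(g.n_per_pool * config.scale)))
        scenario.depth_geometric_mean = max(
            60.0, scenario.depth_geometric_mean * config.scale)
        scenario.depth_geometric_sd = min(
            scenario.depth_geometric_sd, 1 + 2.8 * config.scale)
    return scenario


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage on the default synthetic scenario.

    Stages: simulate reference DB + survey + reads; QC and hierarchical
    classification into a count table; Bray-Curtis dissimilarities with
    a two-way (compartment x pool) PERMANOVA followed by one-way pool
    tests per compartment and coral species; NMDS per compartment;
    Poisson-lognormal differential abundance only where the one-way test
    is significant (unless forced); and Mantel spatial tests per
    compartment/species and pool. Returns a results dict and writes
    TSV/CSV outputs plus the resolved config under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    results: dict = {"config_digest": config.digest()}
    config.to_yaml(outdir / "config.yaml")

    # ---- stage 1: synthetic inputs
    db, truth_db = synth.make_reference_db(
        n_per_clade=config.n_per_clade,
        within_clade_divergence=config.within_clade_divergence,
        between_clade_divergence=config.between_clade_divergence,
        seed=int(rng.integers(2 ** 31)))
    scenario = _scaled_scenario(config)
    true_table, truth_comm = synth.simulate_community(
        scenario, db, truth_db, seed=int(rng.integers(2 ** 31)))
    reads, truth_reads = synth.simulate_reads(
        true_table, db, truth_db, error_rate=scenario.error_rate,
        seed=int(rng.integers(2 ** 31)))
    io.write_reference_db(db, outdir / "db")
    logger.info("simulated %d reads over %d samples", len(reads),
                len(true_table.samples))

    # ---- stage 2: QC + classification
    kept = [r for r in reads if taxonomy.filter_homopolymer(r)]
    results["n_reads"] = len(reads)
    results["n_reads_post_qc"] = len(kept)
    assignments = taxonomy.classify_reads(
        kept, db, e_cutoff=config.e_cutoff, ratio_cutoff=config.ratio_cutoff,
        min_identity=config.min_identity,
        min_ref_coverage=config.min_ref_coverage,
        cluster_identity=config.cluster_identity)
    table, qc = taxonomy.build_count_table(assignments, true_table.metadata)
    table = table.drop_empty_samples()
    io.write_counts(table, outdir / "counts.csv", outdir / "metadata.tsv")
    qc.to_csv(outdir / "qc_report.tsv", sep="\t")
    pd.DataFrame(
        [(a.read_id, a.sample_id, a.label.name, a.label.kind,
          a.label.clade or "") for a in assignments],
        columns=["read_id", "sample_id", "label", "kind", "clade"],
    ).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    results["table"] = table
    results["truth"] = {"db": truth_db, "community": truth_comm,
                        "reads": truth_reads, "true_table": true_table}
    results["qc"] = qc
    results["assignments"] = assignments

    # clade-level composition of the classified table
    clade_totals: dict[str, int] = {}
    leaf_clades = {r.name: r.clade for r in db.records}
    for taxon in table.taxa:
        label = taxonomy.parse_label(taxon, leaf_clades)
        clade = label.clade or "?"
        clade_totals[clade] = clade_totals.get(clade, 0) + int(
            table.counts[taxon].sum())
    results["clade_proportions"] = {
        c: v / sum(clade_totals.values()) for c, v in sorted(clade_totals.items())}

    # ---- stage 3: beta diversity + PERMANOVA
    seed_seq = np.random.SeedSequence(config.seed)
    stat_seeds = iter(seed_seq.spawn(200))

    def next_seed() -> int:
        return int(next(stat_seeds).generate_state(1)[0] % (2 ** 31))

    transformed = community.sqrt_relative(table)
    dm_all = community.bray_curtis(transformed)
    md = table.metadata.loc[list(dm_all.ids)]
    results["permanova_two_way"] = community.permanova(
        dm_all, md, ["compartment", "pool"],
        permutations=config.n_permutations, seed=next_seed())

    subsets: list[tuple[str, dict]] = [
        ("Water", {"compartment": "water"}),
        ("Sediment", {"compartment": "sediment"}),
        ("Coral", {"compartment": "coral"}),
    ]
    for sp in sorted(table.metadata["species"].dropna().unique()):
        subsets.append((sp, {"species": sp}))

    table1_rows = []
    oneway: dict[str, community.PermanovaResult] = {}
    dms: dict[str, object] = {}
    for name, crit in subsets:
        sub = table.subset(**crit).drop_empty_samples().drop_empty_taxa()
        if len(sub.samples) < 4 or sub.metadata["pool"].nunique() < 2:
            continue
        dm = community.bray_curtis(community.sqrt_relative(sub))
        dms[name] = (dm, sub)
        diss = community.group_mean_dissimilarity(
            dm, sub.metadata["pool"])
        res = community.permanova(dm, sub.metadata, "pool",
                                  permutations=config.n_permutations,
                                  seed=next_seed())
        oneway[name] = res
        table1_rows.append({
            "subset": name, "n": len(sub.samples),
            "overall": diss.overall, "within_pool": diss.within,
            "between_pool": diss.between,
            "R2": res["pool"]["R2"], "p": res["pool"]["p"],
        })
    table1 = pd.DataFrame(table1_rows).set_index("subset")
    table1.to_csv(outdir / "table1.tsv", sep="\t")
    results["table1"] = table1
    results["permanova_oneway"] = oneway

    # ---- stage 4: NMDS per compartment
    results["nmds"] = {}
    for name in ("Water", "Sediment", "Coral"):
        if name not in dms:
            continue
        dm, sub = dms[name]
        res = community.nmds(dm, k=2, n_starts=10, seed=next_seed())
        res.coordinates.to_csv(outdir / f"nmds_{name.lower()}.csv")
        results["nmds"][name] = res

    # ---- stage 5: differential abundance (gated on the one-way test)
    spec = diffabund.PlnModelSpec(
        iterations=config.mcmc_iterations, burn_in=config.mcmc_burn_in,
        thin=config.mcmc_thin)
    results["diffabund"] = {}
    for name, crit in subsets:
        if name not in oneway:
            continue
        p = oneway[name]["pool"]["p"]
        if p >= config.alpha and not config.force_diffabund:
            continue
        sub = table.subset(**crit).drop_empty_samples().drop_empty_taxa()
        totals = sub.totals()
        filtered = diffabund.filter_taxa(sub, config.min_fraction)
        if not filtered.taxa:
            continue
        with_sum = diffabund.add_sum_taxon(filtered, totals=totals)
        fit_spec = dataclasses.replace(spec, seed=next_seed())
        posterior = diffabund.fit_pln(with_sum, fit_spec)
        summary = diffabund.summarize_diff(posterior, q=config.fdr_q)
        fname = name.lower().replace(" ", "_")
        summary.table.to_csv(outdir / f"diffabund_{fname}.tsv", sep="\t")
        results["diffabund"][name] = summary

    # ---- stage 6: Mantel tests within pools
    mantel_rows = []
    for name, crit in subsets:
        if name not in dms:
            continue
        for pool in (300, 400):
            sub = table.subset(**crit, pool=pool).drop_empty_samples()
            sub = sub.drop_empty_taxa()
            coords = sub.metadata[["latitude", "longitude"]].dropna()
            if len(coords) < 4:
                continue
            keep = list(coords.index)
            sub = CountTable(sub.counts.loc[keep], sub.metadata.loc[keep])
            positions, _ = spatial.project_positions(sub.metadata)
            d_geo = spatial.geographic_distance(positions)
            d_comm = community.bray_curtis(community.sqrt_relative(sub))
            try:
                res = spatial.mantel(d_geo, d_comm,
                                     permutations=config.n_permutations_mantel,
                                     seed=next_seed())
            except ValueError:
                continue
            mantel_rows.append({"subset": name, "pool": pool, "n": len(keep),
                                "r": res.r, "p": res.p_value,
                                "nperm": res.n_permutations})
    mantel_table = pd.DataFrame(mantel_rows)
    mantel_table.to_csv(outdir / "mantel.tsv", sep="\t", index=False)
    results["mantel"] = mantel_table

    # ---- summary
    two_way = results["permanova_two_way"].table
    summary = {
        "config_digest": config.digest(),
        "n_reads": results["n_reads"],
        "n_samples": len(table.samples),
        "n_taxa": len(table.taxa),
        "clade_proportions": results["clade_proportions"],
        "two_way_p": {term: float(two_way.loc[term, "p"])
                      for term in two_way.index[:-1]},
        "diffabund_subsets": sorted(results["diffabund"]),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return results
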