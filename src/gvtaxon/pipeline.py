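"""End-to-end pipeline orchestration over the synthetic study system.

``run_pipeline`` drives the full procedure in its natural order —
simulate → dereplicate → build profiles → extract markers → concatenate →
infer tree + bootstrap → RED → delineate ranks → score recovery — writing
every stage's tables under an output directory and recording a manifest
of content digests, seeds and backends.  Deterministic stages reproduce
their digests exactly under the same config and seed.

Rank windows default to the "noiseless twin" of the simulation config:
the same taxonomy imprinted on a branch-noise-free tree yields exact
per-rank RED values from which midpoint windows are derived.  This keeps
window derivation deterministic and well-defined even when the inferred
tree is noisy.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Mapping

import dendropy
import pandas as pd

from . import __version__
from .io import (derive_seed, file_digest, write_fasta, write_json,
                 write_newick, write_table, write_tree_list)
from .genome_prep import dereplicate, distances_to_frame
from .markers import (ConcatAlignment, MarkerSetResult, bootstrap_trees,
                      calibrate_cutoff, concatenate, nj_tree,
                      select_orthologs)
from .profiles import build_profile, search_profile
from .red import (DEFAULT_MIN_MEMBERS, RankWindows, apply_anchors,
                  assign_identifiers, compute_red, delineate,
                  derive_rank_windows, recovery_score)
from .synthetic import (RANKS, SimulationConfig, TrueTaxonomy,
                        simulate_genome_set, simulate_marker_alignments,
                        simulate_taxonomy, simulate_tree)
from .tree_support import (NonMonophyleticOutgroupError, root_tree,
                           tree_certainty)

DEFAULT_MARKERS = {
    "A32": 120, "MCP": 200, "PolB": 300, "RNAPL": 280, "RNAPS": 240,
    "SFII": 150, "VLTF3": 100,
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Unknown keys in :meth:`from_dict` are rejected; the resolved config is
    echoed into the run directory so every run is self-describing.
    """

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    markers: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_MARKERS))
    stages: tuple[str, ...] = (
        "simulate", "derep", "gvogs", "markers", "concat", "tree",
        "red", "delineate", "score",
    )
    derep_threshold: float = 0.05
    sketch_k: int = 16
    sketch_size: int = 300
    cutoff_percentile: float = 5.0
    profile_evalue: float = 1e-10
    profile_min_qaf: float = 0.30
    n_boot: int = 100
    min_members: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_MEMBERS))
    windows: dict[str, tuple[float, float]] | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        sim_raw = raw.pop("sim", {})
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        sim_known = {f.name for f in dc_fields(SimulationConfig)}
        sim_unknown = set(sim_raw) - sim_known
        if sim_unknown:
            raise ConfigError(f"unknown sim config keys: {sorted(sim_unknown)}")
        if "divergence_grid" in sim_raw:
            sim_raw["divergence_grid"] = tuple(sim_raw["divergence_grid"])
        if "rank_depth_fractions" in sim_raw:
            sim_raw["rank_depth_fractions"] = tuple(sim_raw["rank_depth_fractions"])
        sim = SimulationConfig(**sim_raw)
        cfg = cls(sim=sim, **raw)
        if "seed" not in raw:
            cfg.seed = sim.seed
        return cfg

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


@dataclass
class StageRecord:
    name: str
    seed: int
    outputs: dict[str, str]  # relative path -> sha256
    wall_clock: float
    status: str = "ok"
    detail: str = ""


@dataclass
class RunManifest:
    version: str
    seed: int
    backend: str
    stages: list[StageRecord] = field(default_factory=list)

    def output_digests(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for st in self.stages:
            out.update(st.outputs)
        return out

    def as_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "backend": self.backend,
            "stages": [dataclasses.asdict(s) for s in self.stages],
        }


def noiseless_windows(config: SimulationConfig,
                      min_taxon_size: int = 2) -> RankWindows:
    """Rank RED windows from the branch-noise-free twin of a simulation.

    Builds the same taxonomy on a noiseless tree, anchors every true taxon
    (taxa need >= ``min_taxon_size`` genomes for an internal MRCA) and
    derives midpoint windows — the analytically known windows of the
    configured study system.
    """
    from .red import rank_red_ranges

    quiet = dataclasses.replace(config, branch_noise=0.0)
    taxonomy = simulate_taxonomy(quiet)
    tree = simulate_tree(taxonomy, quiet)
    red = compute_red(tree)
    # An anchors mapping holds one (rank, name) per genome, so collect the
    # MRCA RED ranges one rank at a time.
    ranges: dict[str, tuple[float, float]] = {}
    for rank in RANKS:
        anchors_r = {}
        for name, members in taxonomy.taxa_at(rank).items():
            if len(members) >= min_taxon_size:
                for g in members:
                    anchors_r[g] = (rank, name)
        if not anchors_r:
            raise ConfigError(
                f"every {rank} has < {min_taxon_size} genomes; cannot derive windows"
            )
        ranges.update(rank_red_ranges(tree, red, anchors_r))
    for a, b in zip(RANKS, RANKS[1:]):
        if ranges[a][1] >= ranges[b][0]:
            raise ConfigError(f"rank RED ranges overlap between {a} and {b}")
    bounds = [ranges[RANKS[0]][0] / 2.0]
    for a, b in zip(RANKS, RANKS[1:]):
        bounds.append((ranges[a][1] + ranges[b][0]) / 2.0)
    bounds.append((ranges[RANKS[-1]][1] + 1.0) / 2.0)
    return RankWindows({r: (bounds[i], bounds[i + 1])
                        for i, r in enumerate(RANKS)})


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunManifest:
    """Execute the enabled stages in order, writing outputs and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(__version__, config.seed, backend="nj_tree")
    write_json(config.as_dict(), outdir / "config.json")

    state: dict[str, Any] = {}

    def record(name: str, seed: int, outputs: list[Path], t0: float,
               status: str = "ok", detail: str = "") -> None:
        manifest.stages.append(
            StageRecord(
                name, seed,
                {p.name: file_digest(p) for p in outputs},
                round(time.time() - t0, 3), status, detail,
            )
        )

    for stage in config.stages:
        t0 = time.time()
        seed = derive_seed(config.seed, stage)
        try:
            outputs = _STAGE_FUNCS[stage](config, state, outdir, seed)
        except Exception as exc:
            record(stage, seed, [], t0, status="failed", detail=str(exc))
            break
        record(stage, seed, outputs, t0)

    write_json(manifest.as_dict(), outdir / "manifest.json")
    return manifest


# --- stage implementations -------------------------------------------------


def _stage_simulate(config, state, outdir, seed):
    sim = config.sim
    taxonomy = simulate_taxonomy(sim)
    tree = simulate_tree(taxonomy, sim)
    names = sorted(config.markers)
    lengths = [config.markers[m] for m in names]
    msim = simulate_marker_alignments(tree, names, lengths, sim)
    gsim = simulate_genome_set(sim)
    state.update(taxonomy=taxonomy, true_tree=tree, marker_sim=msim,
                 genome_sim=gsim)
    outputs = []
    p = outdir / "taxonomy_truth.tsv"
    write_table(taxonomy.to_frame(), p)
    outputs.append(p)
    p = outdir / "true_tree.nwk"
    write_newick(tree, p)
    outputs.append(p)
    for m in names:
        p = outdir / f"marker_{m}.faa"
        write_fasta(msim.alignments[m], p)
        outputs.append(p)
    p = outdir / "marker_truth.tsv"
    write_table(msim.truth, p)
    outputs.append(p)
    p = outdir / "genomes.fna"
    write_fasta(gsim.genomes, p)
    outputs.append(p)
    p = outdir / "genome_divergence_truth.tsv"
    write_table(gsim.truth, p)
    outputs.append(p)
    return outputs


def _stage_derep(config, state, outdir, seed):
    from .genome_prep import GenomeRecord

    gsim = state["genome_sim"]
    records = {
        gid: GenomeRecord(gid, [(f"{gid}_c1", seq)])
        for gid, seq in gsim.genomes.items()
    }
    clusters, reps, dists = dereplicate(
        records, k=config.sketch_k, s=config.sketch_size,
        threshold=config.derep_threshold,
    )
    state["derep"] = (clusters, reps)
    outputs = []
    p = outdir / "derep_distances.tsv"
    write_table(distances_to_frame(dists), p)
    outputs.append(p)
    p = outdir / "derep_clusters.tsv"
    write_table(
        pd.DataFrame(
            [{"cluster": i, "genome_id": g}
             for i, cl in enumerate(clusters) for g in cl]
        ), p)
    outputs.append(p)
    p = outdir / "derep_representatives.tsv"
    write_table(pd.DataFrame({"genome_id": reps}), p)
    outputs.append(p)
    return outputs


def _stage_gvogs(config, state, outdir, seed):
    """Profiles from each marker alignment + all-copy profile search."""
    msim = state["marker_sim"]
    profiles = {}
    rows = []
    for m in sorted(msim.alignments):
        aln = msim.alignments[m]
        orthologs = {k: v for k, v in aln.items() if "|" not in k}
        profiles[m] = build_profile(
            m, orthologs, seed=derive_seed(seed, f"profile:{m}"))
        for seq_id, seq in sorted(aln.items()):
            hit = search_profile(seq_id, seq.replace("-", ""), profiles[m])
            if (hit.evalue <= config.profile_evalue
                    and hit.query_aligned_fraction >= config.profile_min_qaf):
                genome = seq_id.split("|")[0]
                rows.append(
                    {"genome_id": genome, "marker": m, "protein_id": seq_id,
                     "bitscore": hit.bitscore, "evalue": hit.evalue,
                     "qaf": hit.query_aligned_fraction}
                )
    hits = pd.DataFrame(rows)
    state["profiles"] = profiles
    state["raw_hits"] = hits
    p = outdir / "profile_hits.tsv"
    write_table(hits, p)
    return [p]


def _stage_markers(config, state, outdir, seed):
    hits = state["raw_hits"]
    cutoffs = {}
    for m, grp in hits.groupby("marker"):
        best = grp.loc[grp.groupby("genome_id")["bitscore"].idxmax()]
        cutoffs[m] = calibrate_cutoff(best["bitscore"].tolist(),
                                      config.cutoff_percentile)
    table = select_orthologs(hits, cutoffs)
    state["marker_table"] = table
    outputs = []
    p = outdir / "marker_cutoffs.tsv"
    write_table(
        pd.DataFrame(
            [{"marker": m, "cutoff": c} for m, c in sorted(cutoffs.items())]
        ), p)
    outputs.append(p)
    p = outdir / "marker_hits.tsv"
    write_table(table, p)
    outputs.append(p)
    return outputs


def _stage_concat(config, state, outdir, seed):
    msim = state["marker_sim"]
    table = state["marker_table"]
    best = table[table.is_best]
    per_marker: dict[str, dict[str, str]] = {}
    for m in sorted(msim.alignments):
        sel = best[best.marker == m]
        aln = msim.alignments[m]
        per_marker[m] = {
            r.genome_id: aln[r.protein_id] for r in sel.itertuples()
        }
    concat = concatenate(per_marker)
    state["concat"] = concat
    outputs = []
    p = outdir / "concat.faa"
    write_fasta(concat.rows, p)
    outputs.append(p)
    p = outdir / "partitions.txt"
    p.write_text(concat.partition_text())
    outputs.append(p)
    return outputs


def _stage_tree(config, state, outdir, seed):
    concat = state["concat"]
    ref = nj_tree(concat.rows, seed)
    boots = bootstrap_trees(concat, config.n_boot, seed)
    report = tree_certainty(ref, boots)
    state["inferred_tree"] = ref
    state["support"] = report
    outputs = []
    p = outdir / "inferred_tree.nwk"
    write_newick(ref, p)
    outputs.append(p)
    p = outdir / "bootstrap_trees.nwk"
    write_tree_list(boots, p)
    outputs.append(p)
    p = outdir / "support.json"
    write_json(report.as_dict(), p)
    outputs.append(p)
    return outputs


def _stage_red(config, state, outdir, seed):
    taxonomy: TrueTaxonomy = state["taxonomy"]
    unrooted = state["inferred_tree"]
    # Root between the two deepest true groups: outgroup = first class.
    first_class = sorted(taxonomy.taxa_at("class"))[0]
    outgroup = taxonomy.taxa_at("class")[first_class]
    present = {lf.taxon.label for lf in unrooted.leaf_node_iter()}
    outgroup = [g for g in outgroup if g in present]
    try:
        rooted = root_tree(unrooted, outgroup)
        root_method = f"outgroup:{first_class}"
    except (NonMonophyleticOutgroupError, ValueError) as exc:
        rooted = unrooted.clone(depth=1)
        rooted.reroot_at_midpoint()
        rooted.is_rooted = True
        root_method = f"midpoint (outgroup failed: {exc})"
    red = compute_red(rooted)
    state["rooted_tree"] = rooted
    state["red"] = red
    state["root_method"] = root_method
    outputs = []
    p = outdir / "rooted_tree.nwk"
    write_newick(rooted, p)
    outputs.append(p)
    rows = []
    for i, node in enumerate(rooted.preorder_node_iter()):
        rows.append(
            {"node": node.taxon.label if node.taxon else f"internal_{i}",
             "red": red[node], "is_leaf": node.is_leaf()}
        )
    p = outdir / "red_values.tsv"
    write_table(pd.DataFrame(rows), p)
    outputs.append(p)
    return outputs


def _stage_delineate(config, state, outdir, seed):
    rooted = state["rooted_tree"]
    red = state["red"]
    if config.windows is not None:
        windows = RankWindows({r: tuple(v) for r, v in config.windows.items()})
    else:
        windows = noiseless_windows(config.sim)
    assignment = delineate(rooted, red, windows, config.min_members)
    state["windows"] = windows
    state["assignment"] = assignment
    outputs = []
    p = outdir / "windows.json"
    write_json(windows.as_dict(), p)
    outputs.append(p)
    p = outdir / "taxonomy_inferred.tsv"
    write_table(assignment.to_frame(), p)
    outputs.append(p)
    return outputs


def _stage_score(config, state, outdir, seed):
    taxonomy = state["taxonomy"]
    assignment = state["assignment"]
    scores = {}
    for rank in RANKS:
        ari, exact = recovery_score(taxonomy, assignment, rank)
        scores[rank] = {"ari": ari, "exact_match_fraction": exact}
    scores["root_method"] = state.get("root_method", "")
    scores["tc_rel"] = state["support"].tc_rel if "support" in state else None
    state["scores"] = scores
    p = outdir / "recovery_scores.json"
    write_json(scores, p)
    return [p]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "derep": _stage_derep,
    "gvogs": _stage_gvogs,
    "markers": _stage_markers,
    "concat": _stage_concat,
    "tree": _stage_tree,
    "red": _stage_red,
    "delineate": _stage_delineate,
    "score": _stage_score,
}
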