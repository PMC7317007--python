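"""End-to-end orchestration: structure -> partition -> diversity -> trees ->
rank -> primers, with one config, a structured log and a report bundle.

Every stage output is a plain file (FASTA / newick / TSV / JSON) so runs can
be inspected and diffed; a manifest records the configuration, package
versions, seed and collected warnings.  Two runs with the same configuration
and seed produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alignment as alnmod
from . import divstats, phylo, ranking, simulate, structure
from .io import AnnotatedPlastome, read_fasta, read_genbank, write_tsv

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_run_config"]

log = logging.getLogger("plastsurvey")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults mirror the survey protocol."""

    outdir: str = "plastsurvey_out"
    reference_genbank: str | None = None
    alignment_fasta: str | None = None
    simulate: simulate.SimulationConfig | None = None
    reference_taxon: str | None = None
    reference_tree: str | None = None  # newick path; overrides built-in engine
    mask_threshold: float = 0.8
    window: int = 800
    step: int = 200
    bootstrap_full: int = 1000
    bootstrap_marker: int = 100
    weights: tuple[float, float, float] = (1.0, 2.0, 3.0)
    top_k: tuple[int, ...] = (5, 10)
    primer_max_len: float = 900.0
    n_primer_markers: int = 5
    min_ir_len: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.mask_threshold <= 1):
            raise ValueError("mask_threshold must be in (0, 1]")
        for name in ("window", "step", "bootstrap_full", "bootstrap_marker"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def load_run_config(path: str) -> RunConfig:
    """Read a RunConfig from YAML; the ``simulate`` section nests its own keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulate", None)
    if sim is not None:
        plan = sim.pop("marker_plan", None)
        if plan is not None:
            sim["marker_plan"] = [simulate.MarkerSpec(**m) for m in plan]
        sim = simulate.SimulationConfig(**sim)
    for key in ("weights", "top_k"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(simulate=sim, **raw)


def _safe_name(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "_", name)


def _column_to_ref(cmap: alnmod.ColumnMap, column: float) -> int:
    alive = cmap.positions[cmap.positions >= 0]
    return int(np.searchsorted(alive, column))


def _marker_ref_interval(
    cmap: alnmod.ColumnMap, marker: alnmod.MarkerDefinition
) -> tuple[int, int]:
    """Reference interval covered by the marker's columns."""
    alive_idx = np.flatnonzero(cmap.positions >= 0)
    alive_cols = cmap.positions[alive_idx]
    lo = min(s for s, _ in marker.columns)
    hi = max(e for _, e in marker.columns)
    inside = alive_idx[(alive_cols >= lo) & (alive_cols < hi)]
    if inside.size == 0:
        return (0, 0)
    return int(inside.min()), int(inside.max()) + 1


def _write_genbank(plastome: AnnotatedPlastome, path: Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(
        Seq(plastome.sequence.residues),
        id=plastome.sequence.id,
        name=_safe_name(plastome.sequence.id)[:16],
        description="synthetic plastome-like reference",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if plastome.sequence.circular else "linear",
        },
    )
    for feat in plastome.features:
        strand = 1 if feat.strand == "+" else -1
        locs = [SimpleLocation(s, e, strand=strand) for s, e in feat.parts]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        qualifiers = {"gene": [feat.gene_name]}
        if feat.pseudogene:
            qualifiers["pseudo"] = [""]
        rec.features.append(
            SeqFeature(loc, type=feat.feature_class if feat.feature_class != "misc" else "misc_feature", qualifiers=qualifiers)
        )
    from Bio import SeqIO

    SeqIO.write([rec], str(path), "genbank")


def _drop_allgap_taxa(sub: alnmod.MultipleAlignment) -> alnmod.MultipleAlignment:
    keep = [
        (t, r)
        for t, r in zip(sub.taxa, sub.rows)
        if set(r) != {"-"} and r != ""
    ]
    if len(keep) == len(sub.taxa):
        return sub
    return alnmod.MultipleAlignment(
        taxa=[t for t, _ in keep], rows=[r for _, r in keep]
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns a dict of output paths and key objects."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {"outdir": str(outdir)}
    collected_warnings: list[str] = []

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    result = fn()
                for w in caught:
                    collected_warnings.append(f"{name}: {w.message}")
                log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
                return result
            except Exception as err:
                raise PipelineError(f"stage {name!r} failed: {err}") from err

        return wrap

    # ---- inputs ----------------------------------------------------------
    def load_inputs():
        if config.simulate is not None:
            sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
            ds = simulate.simulate_alignment(sim_cfg)
            _write_genbank(ds.reference, outdir / "reference.gb")
            alnmod.write_alignment_fasta(ds.alignment, outdir / "alignment.fasta")
            (outdir / "true_tree.nwk").write_text(ds.true_tree.to_newick() + "\n")
            truth_rows = [
                {
                    "marker": name,
                    "class": t.marker_class,
                    "rate": t.rate,
                    "ref_start": t.interval[0],
                    "ref_end": t.interval[1],
                }
                for name, t in ds.truth.items()
            ]
            write_tsv(pd.DataFrame(truth_rows), outdir / "truth.tsv")
            return ds.reference, ds.alignment
        if not (config.reference_genbank and config.alignment_fasta):
            raise ValueError(
                "either a simulate config or reference_genbank + alignment_fasta is required"
            )
        reference = read_genbank(config.reference_genbank)
        aln = alnmod.read_alignment_fasta(config.alignment_fasta)
        return reference, aln

    reference, aln = stage("inputs")(load_inputs)
    ref_taxon = config.reference_taxon or reference.sequence.id
    outputs["reference"] = reference

    # ---- structure -------------------------------------------------------
    def run_structure():
        if reference.sequence.circular:
            part = structure.find_inverted_repeat(
                reference.sequence, min_len=config.min_ir_len
            )
        else:
            part = structure.RegionPartition(
                genome_length=len(reference.sequence),
                lsc=(0, len(reference.sequence)),
                ssc=(0, 0),
                ira=(0, 0),
                irb=(0, 0),
                ir_length=0,
                degenerate=True,
            )
            warnings.warn("linear reference: degenerate single-copy partition")
        comp = structure.composition_table(reference, part)
        write_tsv(comp, outdir / "composition.tsv")
        (outdir / "partition.json").write_text(
            json.dumps(
                {
                    "genome_length": part.genome_length,
                    "LSC": list(part.lsc),
                    "SSC": list(part.ssc),
                    "IRa": list(part.ira),
                    "IRb": list(part.irb),
                    "ir_length": part.ir_length,
                    "degenerate": part.degenerate,
                },
                indent=2,
            )
            + "\n"
        )
        reports = []
        for feat in reference.features:
            if feat.feature_class != "CDS":
                continue
            rep = structure.screen_pseudogene(
                feat.spliced(reference.sequence), gene_name=feat.gene_name
            )
            reports.append(
                {
                    "gene": feat.gene_name,
                    "flagged": rep.flagged,
                    "reasons": ",".join(sorted(rep.reasons)) or None,
                }
            )
        if reports:
            write_tsv(pd.DataFrame(reports), outdir / "pseudogene_screen.tsv")
        return part

    outputs["partition"] = stage("structure")(run_structure)

    # ---- marker partition ------------------------------------------------
    def run_partition():
        full_cmap = alnmod.build_column_map(aln, ref_taxon)
        masked, removed = alnmod.mask_columns(aln, config.mask_threshold)
        cmap = full_cmap.after_masking(removed, aln.width)
        markers = alnmod.partition_markers(reference, cmap)
        rows = []
        for m in markers:
            rows.append(
                {
                    "marker": m.name,
                    "class": m.marker_class,
                    "n_columns": m.n_columns,
                    "intervals": ";".join(f"{s}-{e}" for s, e in m.columns),
                    "usable": alnmod.marker_usable(masked, m),
                }
            )
        write_tsv(pd.DataFrame(rows), outdir / "markers.tsv")
        return masked, cmap, markers

    masked, cmap, markers = stage("partition")(run_partition)
    outputs["markers"] = markers

    # ---- diversity -------------------------------------------------------
    def run_diversity():
        track = divstats.sliding_window_pi(masked, config.window, config.step)
        win_rows = [
            {
                "start_col": s,
                "mid_col": mid,
                "ref_start": _column_to_ref(cmap, s),
                "pi": pi,
            }
            for s, mid, pi in track.windows
        ]
        write_tsv(pd.DataFrame(win_rows), outdir / "windows_pi.tsv")
        overall = divstats.nucleotide_diversity(masked)
        metrics: dict[str, ranking.MarkerMetrics] = {}
        for m in markers:
            sub = alnmod.extract_marker(masked, m)
            sc = divstats.site_classes(sub)
            metrics[m.name] = ranking.MarkerMetrics(
                name=m.name,
                marker_class=m.marker_class,
                mean_length=sc.mean_ungapped_length,
                aligned_length=sc.aligned_length,
                variable_sites=sc.variable_sites,
                parsimony_informative_sites=sc.parsimony_informative_sites,
                gap_sites=sc.gap_sites,
                mean_k80=divstats.mean_k80(sub),
            )
        return overall, metrics

    overall_pi, metrics = stage("diversity")(run_diversity)
    outputs["pi"] = overall_pi

    # ---- trees -----------------------------------------------------------
    def run_trees():
        if config.reference_tree:
            full_tree = phylo.UnrootedTree.from_newick(
                Path(config.reference_tree).read_text()
            )
        else:
            full_tree = phylo.bootstrap_support(
                masked, B=config.bootstrap_full, seed=config.seed
            )
        (outdir / "full_tree.nwk").write_text(full_tree.to_newick() + "\n")
        treedir = outdir / "marker_trees"
        treedir.mkdir(exist_ok=True)
        for idx, m in enumerate(markers):
            if not alnmod.marker_usable(masked, m):
                continue
            sub = _drop_allgap_taxa(alnmod.extract_marker(masked, m))
            if sub.n_taxa < 4:
                continue
            try:
                mtree = phylo.bootstrap_support(
                    sub, B=config.bootstrap_marker, seed=config.seed + idx + 1
                )
            except (divstats.UndefinedDistanceError, ValueError) as err:
                warnings.warn(f"marker {m.name!r}: no tree ({err})")
                continue
            (treedir / f"{_safe_name(m.name)}.nwk").write_text(
                mtree.to_newick() + "\n"
            )
            pruned = (
                full_tree.prune_to(mtree.leaves)
                if mtree.leaves != full_tree.leaves
                else full_tree
            )
            metrics[m.name].mean_bootstrap = phylo.mean_support(mtree)
            metrics[m.name].tree_distance = phylo.rf_distance(mtree, pruned)
        return full_tree

    full_tree = stage("trees")(run_trees)
    outputs["full_tree"] = full_tree

    # ---- metrics table ---------------------------------------------------
    def run_metrics_table():
        rows = []
        for m in markers:
            mm = metrics[m.name]
            rows.append(
                {
                    "marker": mm.name,
                    "class": mm.marker_class,
                    "bp_mean": round(mm.mean_length, 1),
                    "aligned_bp": mm.aligned_length,
                    "variable": mm.variable_sites,
                    "pis": mm.parsimony_informative_sites,
                    "sites_with_gaps": mm.gap_sites,
                    "mean_k80": None if mm.mean_k80 is None else round(mm.mean_k80, 5),
                    "tree_distance": mm.tree_distance,
                    "bootstrap_mean": (
                        None
                        if mm.mean_bootstrap is None
                        else round(mm.mean_bootstrap, 1)
                    ),
                }
            )
        write_tsv(pd.DataFrame(rows), outdir / "metrics.tsv")

    stage("metrics")(run_metrics_table)

    # ---- ranking + top-k datasets ---------------------------------------
    def run_rank():
        w1, w2, w3 = config.weights
        rcfg = ranking.RankingConfig(
            weight_variable=w1, weight_bootstrap=w2, weight_distance=w3
        )
        ranked = ranking.rank_markers(list(metrics.values()), rcfg)
        write_tsv(
            pd.DataFrame(
                [
                    {
                        "rank": r.rank,
                        "marker": r.name,
                        "score": round(r.score, 5),
                        "r_var": round(r.r_var, 5),
                        "r_bs": round(r.r_bs, 5),
                        "r_dist": round(r.r_dist, 5),
                    }
                    for r in ranked
                ]
            ),
            outdir / "ranked.tsv",
        )
        by_name = {m.name: m for m in markers}
        for k in config.top_k:
            if k > len(ranked):
                warnings.warn(f"top-{k} requested but only {len(ranked)} ranked")
                continue
            names = ranking.select_top(ranked, k)
            concat = ranking.concatenate_markers(
                masked, [by_name[n] for n in names]
            )
            alnmod.write_alignment_fasta(concat, outdir / f"top{k}.fasta")
            sub = _drop_allgap_taxa(concat)
            if sub.n_taxa >= 4:
                ktree = phylo.bootstrap_support(
                    sub, B=config.bootstrap_full, seed=config.seed
                )
                (outdir / f"top{k}_tree.nwk").write_text(ktree.to_newick() + "\n")
        return ranked

    ranked = stage("rank")(run_rank)
    outputs["ranked"] = ranked

    # ---- primers ---------------------------------------------------------
    def run_primers():
        ranked_names = [r.name for r in ranked]
        small = {m.name for m in ranking.size_filter(
            [metrics[n] for n in ranked_names], config.primer_max_len
        )}
        chosen = [n for n in ranked_names if n in small][: config.n_primer_markers]
        by_name = {m.name: m for m in markers}
        rows = []
        for name in chosen:
            target = _marker_ref_interval(cmap, by_name[name])
            if target[1] <= target[0]:
                continue
            pair, tally = ranking.pick_primers(reference, target)
            if pair is None:
                rows.append({"marker": name, "status": f"infeasible:{tally}"})
                continue
            rows.append(
                {
                    "marker": name,
                    "status": "ok",
                    "forward": pair.forward,
                    "reverse": pair.reverse,
                    "forward_tm": round(pair.forward_tm, 2),
                    "reverse_tm": round(pair.reverse_tm, 2),
                    "forward_gc": round(pair.forward_gc, 1),
                    "reverse_gc": round(pair.reverse_gc, 1),
                    "product_size": pair.product_size,
                }
            )
        write_tsv(
            pd.DataFrame(rows if rows else [{"marker": None, "status": "none"}]),
            outdir / "primers.tsv",
        )
        return rows

    outputs["primers"] = stage("primers")(run_primers)

    # ---- manifest --------------------------------------------------------
    def run_manifest():
        import Bio
        import dendropy

        from . import __version__

        cfg = dataclasses.asdict(config)
        cfg.pop("outdir", None)  # path choice must not break report identity
        manifest = {
            "config": cfg,
            "seed": config.seed,
            "versions": {
                "plastsurvey": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "biopython": Bio.__version__,
                "dendropy": dendropy.__version__,
            },
            "warnings": collected_warnings,
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str) + "\n"
        )

    stage("manifest")(run_manifest)
    return outputs
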