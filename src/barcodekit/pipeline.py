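"""End-to-end report pipelines.

``run_molecular_pipeline`` chains distances -> NJ tree (+bootstrap) ->
barcode-gap summary -> OTU clustering -> diagnostic sites, writing one
report file per stage plus a run log; stages hand their results to each
other in memory. ``run_morphology_pipeline`` writes the character summary,
both discriminant analyses (meristic and morphometric) and per-specimen
identification-key calls. Any stage failure aborts the run and removes the
partially written bundle.

Report percentages are rendered with 2 decimals (half-up) unless
``full_precision`` is set.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .barcode_gap import level_summaries, species_summaries
from .diagnostics import combination_signature, diagnostic_sites
from .distances import distance_matrix, round_half_up
from .morphology import (
    MorphTable,
    discriminant_analysis,
    identification_key,
    select_dfa_variables,
    summarize_characters,
)
from .otu_cluster import (
    DEFAULT_THRESHOLD_PCT,
    concordance_report,
    single_linkage_otus,
)
from .seqio import read_fasta_with_metadata, write_newick
from .treebuild import bootstrap_support, nj_tree

logger = logging.getLogger("barcodekit")

__all__ = ["PipelineConfig", "run_molecular_pipeline",
           "run_morphology_pipeline"]


@dataclass
class PipelineConfig:
    fasta: str | None = None
    metadata: str | None = None
    morphology: str | None = None
    outdir: str = "barcodekit_out"
    model: str = "k2p"
    bootstrap_replicates: int = 1000
    seed: int = 0
    otu_threshold: float = DEFAULT_THRESHOLD_PCT
    min_support: float = 50.0
    full_precision: bool = False
    extra: dict = field(default_factory=dict)


def _fmt_pct(x: float | None, full: bool) -> object:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return x if full else round_half_up(x, 2)


class _Bundle:
    """Tracks written outputs so a failed run leaves nothing behind."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.written: list[Path] = []
        outdir.mkdir(parents=True, exist_ok=True)

    def path(self, name: str) -> Path:
        p = self.outdir / name
        self.written.append(p)
        return p

    def cleanup(self) -> None:
        for p in self.written:
            p.unlink(missing_ok=True)


def run_molecular_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run the molecular stages and write the report bundle.

    Returns a mapping of report name to written path.
    """
    if not (cfg.fasta and cfg.metadata):
        raise ValueError("molecular pipeline needs fasta and metadata paths")
    bundle = _Bundle(Path(cfg.outdir))
    log_lines = [
        f"barcodekit {__version__}",
        f"inputs: fasta={cfg.fasta} metadata={cfg.metadata}",
        f"model={cfg.model} bootstrap={cfg.bootstrap_replicates} "
        f"seed={cfg.seed} otu_threshold={cfg.otu_threshold}%",
    ]
    try:
        aln = read_fasta_with_metadata(cfg.fasta, cfg.metadata)
        species_map = aln.species_map()
        log_lines.append(f"alignment: {len(aln)} records x {aln.length} sites")

        dm = distance_matrix(aln, model=cfg.model)
        undef = dm.undefined_pairs
        log_lines.append(f"undefined distance pairs: {len(undef)}")
        for pair in undef:
            log_lines.append(f"  undefined: {pair[0]} vs {pair[1]}")
        pct = pd.DataFrame(dm.values * 100.0, index=dm.labels,
                           columns=dm.labels)
        if not cfg.full_precision:
            pct = pct.map(lambda v: round_half_up(v, 2))
        pct.to_csv(bundle.path("dist.csv"), index_label="specimen_id")

        if cfg.bootstrap_replicates > 0:
            tree = bootstrap_support(
                aln, model=cfg.model, replicates=cfg.bootstrap_replicates,
                seed=cfg.seed)
        else:
            tree = nj_tree(dm)
        write_newick(tree, bundle.path("tree.nwk"),
                     min_support=cfg.min_support)
        log_lines.append(
            f"tree: clamped negative branch total {tree.clamped_deficit:g}")

        rows = []
        for s in species_summaries(dm, species_map):
            rows.append({
                "species": s.species,
                "specimens": s.n_specimens,
                "mean_distance": _fmt_pct(s.mean_intra, cfg.full_precision),
                "sd": _fmt_pct(s.sd_intra, cfg.full_precision),
                "minimum_distance": _fmt_pct(s.min_intra, cfg.full_precision),
                "maximum_distance": _fmt_pct(s.max_intra, cfg.full_precision),
                "nearest_neighbor": s.nearest_neighbor,
                "distance_to_nearest_neighbor": _fmt_pct(
                    s.nn_distance, cfg.full_precision),
                "barcoding_gap": (
                    _fmt_pct(s.barcode_gap, cfg.full_precision)
                    if s.barcode_gap is not None
                    else ("no gap" if s.has_gap is False else "")),
            })
        pd.DataFrame(rows).to_csv(bundle.path("gap_summary.csv"), index=False)
        for lv in level_summaries(dm, species_map):
            log_lines.append(
                f"{lv.level}: {lv.min:.2f}-{lv.max:.2f}% "
                f"(mean {lv.mean:.2f}%, {lv.n_pairs} pairs)")

        partition = single_linkage_otus(dm, threshold=cfg.otu_threshold)
        pd.DataFrame(
            concordance_report(partition, species_map)
        ).to_csv(bundle.path("otus.csv"), index=False)
        log_lines.append(f"otus: {partition.n_clusters} clusters at "
                         f"{cfg.otu_threshold}%")

        table = diagnostic_sites(aln, species_map)
        diag_rows = []
        for site in table.sites:
            row = {"position": site.position}
            for sp in table.species:
                row[sp] = site.states[sp] or "."
            row["diagnostic_for"] = site.diagnostic_for or ""
            diag_rows.append(row)
        pd.DataFrame(
            diag_rows,
            columns=["position", *table.species, "diagnostic_for"],
        ).to_csv(bundle.path("diagnostics.csv"), index=False)
        for sp in table.species:
            sig = combination_signature(table, sp)
            log_lines.append(
                f"combination signature {sp}: "
                f"{'/'.join(s or '.' for s in sig.states)} "
                f"({'unique' if sig.identifiable else 'not identifiable'})")

        bundle.path("run.log").write_text(
            "\n".join(log_lines) + "\n", encoding="utf-8")
    except Exception:
        bundle.cleanup()
        raise
    return {p.name: p for p in bundle.written}


def run_morphology_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run the morphology stages and write the report bundle."""
    if not cfg.morphology:
        raise ValueError("morphology pipeline needs a morphology CSV path")
    bundle = _Bundle(Path(cfg.outdir))
    log_lines = [f"barcodekit {__version__}",
                 f"inputs: morphology={cfg.morphology}"]
    try:
        t = MorphTable.from_csv(cfg.morphology)
        log_lines.append(f"table: {len(t)} specimens, "
                         f"{len(t.species)} species")
        summarize_characters(t).to_csv(bundle.path("morph_summary.csv"),
                                       index=False)

        for mode in ("meristic", "morphometric"):
            variables = select_dfa_variables(t, mode)
            res = discriminant_analysis(t, variables)
            log_lines.append(
                f"dfa {mode}: {len(variables)} variables, "
                f"{res.n_functions} functions, dropped {res.n_dropped} "
                f"incomplete specimens")
            coef = pd.DataFrame(
                res.std_coefficients, index=res.variables,
                columns=[f"DF{k+1}" for k in range(res.n_functions)])
            coef.loc["Percentage of explained variance"] = res.explained_pct
            coef.loc["Eigenvalue"] = res.eigenvalues
            coef.loc["Cumulative variance in %"] = np.cumsum(
                res.explained_pct)
            coef.to_csv(bundle.path(f"dfa_{mode}_coefficients.csv"),
                        index_label="character")
            res.scores.to_csv(bundle.path(f"dfa_{mode}_scores.csv"),
                              index_label="specimen_id")
            stats_obj = {
                "wilks_lambda": res.wilks_lambda,
                "bartlett_chi2": res.bartlett_chi2,
                "bartlett_df": res.bartlett_df,
                "bartlett_p": res.bartlett_p,
                "boxm_stat": res.boxm_stat,
                "boxm_chi2": res.boxm_chi2,
                "boxm_df": res.boxm_df,
                "boxm_p": res.boxm_p,
                "eigenvalues": res.eigenvalues.tolist(),
                "explained_pct": res.explained_pct.tolist(),
                "warnings": res.warnings,
            }
            bundle.path(f"dfa_{mode}_stats.json").write_text(
                json.dumps(stats_obj, indent=2, default=float) + "\n",
                encoding="utf-8")

        id_rows = []
        for _, row in t.df.iterrows():
            r = identification_key(row)
            id_rows.append({
                "specimen_id": row["specimen_id"],
                "labelled_species": row["species"],
                "key_genus": r.genus or "",
                "key_species": r.species or "",
                "status": r.status,
                "matched": r.n_matched,
                "evaluated": r.n_evaluated,
            })
        pd.DataFrame(id_rows).to_csv(bundle.path("identifications.csv"),
                                     index=False)
        bundle.path("run.log").write_text(
            "\n".join(log_lines) + "\n", encoding="utf-8")
    except Exception:
        bundle.cleanup()
        raise
    return {p.name: p for p in bundle.written}
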