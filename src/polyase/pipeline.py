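"""End-to-end orchestration: consensus -> dSNPs -> ASE -> imbalance.

The pipeline consumes one mpileup text file per parental strain plus one
per polyploid individual, all aligned to the same transcriptome reference,
and emits per-strain consensus tables, the dSNP table, per-individual ASE
tables and imbalance classifications, together with a funnel of per-stage
record counts (positions evaluated -> informational sites -> dSNPs in
complete transcripts) for comparison against real-data runs. Any ploidy
>= 2 is supported; a "triploid" sample below is simply the polyploid
individual being measured.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import consensus as cns
from . import dsnp as dsnp_mod
from . import expression as expr
from . import imbalance as imb
from .formats import read_fasta, read_mpileup, write_table

__all__ = [
    "RunConfig",
    "load_config",
    "run_end_to_end",
    "mean_dsnps_per_transcript",
    "PipelineError",
]

logger = logging.getLogger("polyase")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and record."""


@dataclasses.dataclass
class RunConfig:
    """Inputs, thresholds and output location for one pipeline run."""

    reference: Path
    strains: Dict[str, Path]  # parental strain name -> mpileup path
    triploids: Dict[str, Path]  # polyploid individual name -> mpileup path
    out_dir: Path
    annotation: Path | None = None
    thresholds: cns.Thresholds = dataclasses.field(default_factory=cns.Thresholds)
    alpha: float = 0.01
    fold: float = 2.0
    cv_threshold: float = imb.CV_ONE_SILENCED
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.strains) < 2:
            raise ValueError("polyploid ASE needs at least two parental strains")
        self.reference = Path(self.reference)
        self.out_dir = Path(self.out_dir)
        self.strains = {k: Path(v) for k, v in self.strains.items()}
        self.triploids = {k: Path(v) for k, v in self.triploids.items()}
        if self.annotation is not None:
            self.annotation = Path(self.annotation)


def load_config(path: str | Path) -> RunConfig:
    """Load a flat YAML run configuration."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    threshold_keys = {f.name for f in dataclasses.fields(cns.Thresholds)}
    thresholds = cns.Thresholds(
        **{k: raw.pop(k) for k in list(raw) if k in threshold_keys}
    )
    return RunConfig(thresholds=thresholds, **raw)


def mean_dsnps_per_transcript(n_dsnps: int, n_transcripts: int) -> float:
    """Funnel summary: average dSNP count per ASE-compatible transcript."""
    if n_transcripts == 0:
        return math.nan
    return n_dsnps / n_transcripts


def _process_parent(
    path: Path,
    references: Mapping[str, str],
    thresholds: cns.Thresholds,
    consensus_out: Path,
    strain: str,
) -> Tuple[Dict[str, str], Dict[str, np.ndarray], int]:
    """One streaming pass over a parental pileup.

    Returns (IUPAC track per transcript, depth vector per transcript,
    positions evaluated). Uncovered positions keep 'N' in the track and 0
    depth.
    """
    tracks = {tid: bytearray(b"N" * len(seq)) for tid, seq in references.items()}
    depths = {tid: np.zeros(len(seq), dtype=np.int32) for tid, seq in references.items()}
    n_positions = 0
    with open(consensus_out, "w") as out:
        out.write("transcript_id\tposition\tref\tiupac\tdepth\tvar_freq\tp\tflags\n")
        for column in read_mpileup(path):
            tid = column.transcript_id
            if tid not in tracks:
                raise PipelineError(
                    f"consensus[{strain}]: pileup transcript {tid!r} absent from reference"
                )
            if column.position > len(references[tid]):
                raise PipelineError(
                    f"consensus[{strain}]: position {column.position} beyond {tid} length"
                )
            call = cns.call_consensus(
                cns.tally_bases(column, thresholds.min_base_quality),
                column.ref_base,
                thresholds,
            )
            n_positions += 1
            tracks[tid][column.position - 1] = ord(call.iupac)
            depths[tid][column.position - 1] = column.depth
            flags = ",".join(sorted(call.flags))
            out.write(
                f"{tid}\t{column.position}\t{column.ref_base}\t{call.iupac}\t"
                f"{call.depth}\t{call.variant_frequency:.4g}\t{call.p_value:.4g}\t{flags}\n"
            )
    return (
        {tid: track.decode() for tid, track in tracks.items()},
        depths,
        n_positions,
    )


def _process_triploid(
    path: Path,
    references: Mapping[str, str],
    dsnp_index: Mapping[Tuple[str, int], Sequence[Tuple[str, str]]],
    name: str,
) -> Tuple[Dict[str, np.ndarray], Dict[Tuple[str, int], Tuple[int, Dict[str, int]]]]:
    """One streaming pass over a polyploid sample's pileup.

    Returns depth vectors and, at every dSNP position, the covering-read
    count n together with per-strain discriminating-base counts n_s.
    """
    depths = {tid: np.zeros(len(seq), dtype=np.int32) for tid, seq in references.items()}
    site_counts: Dict[Tuple[str, int], Tuple[int, Dict[str, int]]] = {}
    for column in read_mpileup(path):
        tid = column.transcript_id
        if tid not in depths:
            raise PipelineError(
                f"ase[{name}]: pileup transcript {tid!r} absent from reference"
            )
        depths[tid][column.position - 1] = column.depth
        key = (tid, column.position)
        entries = dsnp_index.get(key)
        if entries:
            bases = column.bases
            per_strain = {
                strain: bases.count(base) + bases.count(base.lower())
                for strain, base in entries
            }
            site_counts[key] = (column.depth, per_strain)
    return depths, site_counts


def run_end_to_end(config: RunConfig) -> Dict[str, object]:
    """Run the full pipeline and write all report files.

    Returns a dict with output paths and the per-stage record counts.
    Deterministic given the configuration: re-running byte-reproduces every
    output.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    counts: Dict[str, object] = {}
    paths: Dict[str, object] = {}

    # --- reference -------------------------------------------------------
    try:
        reference = read_fasta(config.reference)
    except Exception as exc:
        raise PipelineError(f"reference: {exc}") from exc
    references = {rec.id: rec.sequence for rec in reference}
    counts["reference_transcripts"] = len(references)
    logger.info("reference: %d transcripts", len(references))

    # --- per-strain consensus -------------------------------------------
    tracks: Dict[str, Dict[str, str]] = {}
    parent_depths: Dict[str, Dict[str, np.ndarray]] = {}
    for strain, pileup_path in config.strains.items():
        consensus_path = out / f"consensus_{strain}.tsv"
        tracks[strain], parent_depths[strain], n_pos = _process_parent(
            pileup_path, references, config.thresholds, consensus_path, strain
        )
        paths[f"consensus_{strain}"] = consensus_path
        counts[f"positions_evaluated_{strain}"] = n_pos
        logger.info("consensus[%s]: %d positions evaluated", strain, n_pos)

    # --- dSNP discovery --------------------------------------------------
    try:
        all_dsnps = dsnp_mod.find_dsnps(tracks, references)
    except ValueError as exc:
        raise PipelineError(f"dsnp: {exc}") from exc
    counts["informational_sites"] = len({(d.transcript_id, d.position) for d in all_dsnps})
    counts["dsnps_total"] = len(all_dsnps)
    kept_transcripts, kept_dsnps = dsnp_mod.select_complete_transcripts(
        all_dsnps, config.strains
    )
    counts["dsnp_complete_transcripts"] = len(kept_transcripts)
    counts["dsnps_in_complete_transcripts"] = len(kept_dsnps)
    counts["mean_dsnps_per_transcript"] = mean_dsnps_per_transcript(
        len(kept_dsnps), len(kept_transcripts)
    )
    logger.info(
        "dsnp: %d informational sites, %d dSNPs, %d complete transcripts",
        counts["informational_sites"], len(all_dsnps), len(kept_transcripts),
    )
    dsnp_path = out / "dsnps.tsv"
    write_table(
        [
            {
                "transcript_id": d.transcript_id,
                "position": d.position,
                "strain": d.strain,
                "base": d.base,
                "others": ";".join(
                    f"{s}:{''.join(sorted(exp))}" for s, exp in sorted(d.other_bases.items())
                ),
            }
            for d in kept_dsnps
        ],
        dsnp_path,
        columns=["transcript_id", "position", "strain", "base", "others"],
    )
    paths["dsnps"] = dsnp_path

    dsnp_index: Dict[Tuple[str, int], List[Tuple[str, str]]] = {}
    for d in kept_dsnps:
        dsnp_index.setdefault((d.transcript_id, d.position), []).append((d.strain, d.base))
    dsnps_by_transcript: Dict[str, List[dsnp_mod.Dsnp]] = {}
    for d in kept_dsnps:
        dsnps_by_transcript.setdefault(d.transcript_id, []).append(d)

    # --- coverage and size factors --------------------------------------
    triploid_depths: Dict[str, Dict[str, np.ndarray]] = {}
    triploid_sites: Dict[str, Dict[Tuple[str, int], Tuple[int, Dict[str, int]]]] = {}
    for name, pileup_path in config.triploids.items():
        triploid_depths[name], triploid_sites[name] = _process_triploid(
            pileup_path, references, dsnp_index, name
        )

    sample_depths: Dict[str, Dict[str, np.ndarray]] = {**parent_depths, **triploid_depths}
    g_matrix = pd.DataFrame(
        {
            sample: {
                tid: expr.geometric_mean_depth(depth) for tid, depth in depths.items()
            }
            for sample, depths in sample_depths.items()
        }
    )
    try:
        factors = expr.size_factors(g_matrix)
    except ValueError:
        # Degenerate input (e.g. empty pileups): fall back to unit factors.
        factors = pd.Series(1.0, index=g_matrix.columns)
        logger.warning("size factors undefined; using unit factors")
    normalized_g = g_matrix.div(factors, axis=1)
    counts["size_factors"] = {k: float(v) for k, v in factors.items()}

    # --- ASE per polyploid individual ------------------------------------
    strain_names = list(config.strains)
    ase_tables: Dict[str, pd.DataFrame] = {}
    for name in config.triploids:
        sites = triploid_sites[name]
        rows = []
        for tid in kept_transcripts:
            g = float(normalized_g.loc[tid, name])
            fractional: Dict[str, List[float]] = {s: [] for s in strain_names}
            for d in dsnps_by_transcript[tid]:
                n, per_strain = sites.get((tid, d.position), (0, {}))
                obs = expr.DsnpObservation(d, n, per_strain.get(d.strain, 0))
                fractional[d.strain].append(expr.fractional_expression(g, obs))
            record = expr.ase_values(tid, fractional)
            rows.append(
                {
                    "transcript_id": tid,
                    **record.values,
                    "whole_gene_expression": record.whole_gene_expression,
                }
            )
        frame = pd.DataFrame(
            rows, columns=["transcript_id", *strain_names, "whole_gene_expression"]
        )
        ase_path = out / f"ase_{name}.tsv"
        write_table(frame, ase_path, float_format="%.6f")
        paths[f"ase_{name}"] = ase_path
        ase_tables[name] = frame.set_index("transcript_id")
        counts[f"ase_transcripts_{name}"] = len(frame)
        logger.info("ase[%s]: %d transcripts", name, len(frame))

    # --- imbalance per polyploid individual ------------------------------
    parent_names = list(config.strains)
    parental_mean = normalized_g[parent_names].mean(axis=1)
    category_maps: Dict[str, Dict[str, str]] = {}
    for name, table in ase_tables.items():
        records: List[imb.ImbalanceRecord] = []
        skipped = 0
        for tid, row in table.iterrows():
            values = {s: float(row[s]) for s in strain_names}
            total = sum(values.values())
            p_mean = float(parental_mean.loc[tid])
            if total <= 0 or p_mean <= 0:
                skipped += 1
                continue
            cv = imb.coefficient_of_variation(list(values.values()))
            p_equal = imb.equal_expression_test(list(values.values()))
            category = imb.classify_category(values, p_equal, config.alpha, config.fold)
            quad = imb.quadrant(total, p_mean, cv, config.fold, config.cv_threshold)
            records.append(
                imb.ImbalanceRecord(
                    tid, cv, p_equal, category, quad, math.log2(total / p_mean)
                )
            )
        imb_path = out / f"imbalance_{name}.tsv"
        write_table(
            [dataclasses.asdict(r) for r in records],
            imb_path,
            columns=["transcript_id", "cv", "p_equal", "category", "quadrant", "fold_change"],
        )
        paths[f"imbalance_{name}"] = imb_path
        counts[f"imbalance_transcripts_{name}"] = len(records)
        counts[f"imbalance_skipped_{name}"] = skipped
        category_maps[name] = {r.transcript_id: r.category for r in records}
        if config.annotation is not None:
            annotation = pd.read_csv(config.annotation, sep="\t")
            rank_path = out / f"chromosome_ranks_{name}.tsv"
            write_table(
                imb.chromosome_rank_table(category_maps[name], annotation), rank_path
            )
            paths[f"chromosome_ranks_{name}"] = rank_path

    # --- cross-individual concordance ------------------------------------
    names = list(category_maps)
    if len(names) >= 2:
        a, b = names[0], names[1]
        shared = sorted(set(category_maps[a]) & set(category_maps[b]))
        total, per_category = imb.concordance(
            {t: category_maps[a][t] for t in shared},
            {t: category_maps[b][t] for t in shared},
        )
        counts["concordant_transcripts"] = total
        counts["concordance_by_category"] = per_category
        logger.info("concordance[%s vs %s]: %d transcripts", a, b, total)

    summary_path = out / "run_summary.json"
    with open(summary_path, "w") as handle:
        json.dump(counts, handle, indent=2, sort_keys=True)
        handle.write("\n")
    paths["summary"] = summary_path
    return {"paths": paths, "counts": counts}
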