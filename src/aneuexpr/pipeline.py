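"""End-to-end orchestration: quantify -> dosage scan -> DE -> cis/trans
-> compensation, with TSV tables per stage and one JSON summary.

Stage order mirrors the analysis logic: the karyotype shift is
detected first from chromosome-level expression, DEGs are then called
for every pairwise group comparison, partitioned into cis and trans
effects using the declared karyotypes, overlapped across comparisons,
and finally the one-dose genes on any reduced chromosome are
classified into compensation classes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import cistrans, compensation, diffexpr, dosage, io, quantify

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """Failure inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj) if isinstance(obj, set)] if isinstance(
            obj, set
        ) else [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if obj is pd.NA or (isinstance(obj, float) and np.isnan(obj)):
        return None
    return obj


def run_pipeline(config: io.RunConfig) -> dict:
    """Run every analysis stage and write the report bundle.

    Returns the summary dict (also written as ``summary.json``).  On
    any stage failure, files written so far are removed and a
    :class:`PipelineError` naming the stage is raised.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(frame: pd.DataFrame, name: str, index: bool = True) -> None:
        path = out_dir / name
        frame.to_csv(path, sep="\t", index=index)
        written.append(path)

    summary: dict = {
        "thresholds": {
            "fc_threshold": config.fc_threshold,
            "q_threshold": config.q_threshold,
            "alpha": config.alpha,
            "min_genes": config.min_genes,
            "bin_edges": list(config.bin_edges),
        },
        "seed": config.seed,
        "de_test": "welch_t_log2_fpkm_plus_1",
    }
    stage = "read_inputs"
    try:
        counts = io.read_counts(config.counts)
        genes = io.read_annotation(config.annotation)
        samples = io.read_sample_sheet(config.samples)
        karyotypes = io.read_karyotypes(config.karyotypes)

        stage = "quantify"
        expr = quantify.compute_fpkm(counts, genes)
        euploids = [g for g, k in karyotypes.items() if k.is_euploid()]
        if len(euploids) != 1:
            raise ValueError(f"need exactly one euploid group, found {euploids}")
        euploid = euploids[0]
        groups = [g for g in samples["group"].unique() if g in karyotypes]
        aneuploids = [g for g in groups if g != euploid]

        stage = "dosage_scan"
        summary["dosage"] = {}
        for g in aneuploids:
            calls = dosage.scan_dosage(
                expr, genes, samples, test=g, reference=euploid, min_genes=config.min_genes
            )
            _write(calls, f"dosage_{g}.tsv", index=False)
            summary["dosage"][g] = {
                row.chromosome: {
                    "call": row.call,
                    "estimated_copies": row.estimated_copies,
                    "median_log2_ratio": row.median_log2_ratio,
                    "n_genes_used": row.n_genes_used,
                }
                for row in calls.itertuples()
            }

        stage = "diffexpr"
        comparisons = [(euploid, g) for g in aneuploids]
        comparisons += [
            (aneuploids[i], aneuploids[j])
            for i in range(len(aneuploids))
            for j in range(i + 1, len(aneuploids))
        ]
        deg_tables: dict[str, pd.DataFrame] = {}
        summary["comparisons"] = {}
        for ref, test in comparisons:
            name = f"{ref}_vs_{test}"
            table = diffexpr.call_degs(
                expr,
                samples,
                test=test,
                reference=ref,
                fc_threshold=config.fc_threshold,
                q_threshold=config.q_threshold,
            )
            deg_tables[name] = table
            _write(table, f"degs_{name}.tsv")
            summary["comparisons"][name] = diffexpr.summarize_comparison(name, table).to_dict()

        stage = "cis_trans"
        trans_tables: dict[str, pd.DataFrame] = {}
        for ref, test in comparisons:
            name = f"{ref}_vs_{test}"
            altered = cistrans.altered_chromosomes(karyotypes[test], karyotypes[ref])
            reduced = karyotypes[test].reduced_vs(karyotypes[ref])
            part = cistrans.partition_degs(
                deg_tables[name], genes, altered, reduced=reduced, comparison=name
            )
            trans_tables[name] = part.trans
            _write(part.labeled_table(), f"cistrans_{name}.tsv")
            expressed = expr.index[
                (quantify.mean_group_expression(expr, samples, test) > 0)
                | (quantify.mean_group_expression(expr, samples, ref) > 0)
            ]
            susc = cistrans.chromosome_susceptibility(deg_tables[name], expressed, genes, altered)
            _write(susc, f"susceptibility_{name}.tsv", index=False)
            summary["comparisons"][name].update(
                {
                    "altered_chromosomes": sorted(altered),
                    "n_cis": len(part.cis),
                    "n_trans": len(part.trans),
                    "pct_trans": part.pct_trans,
                    "trans_up": int((part.trans["direction"] == "up").sum()),
                    "trans_down": int((part.trans["direction"] == "down").sum()),
                    "trans_bias_p": part.trans_bias.p if part.trans_bias else None,
                    "cis_up_count": part.cis_up_count,
                    "n_unlocated": part.n_unlocated,
                }
            )

        stage = "overlap"
        summary["venn"] = {}
        if len(deg_tables) >= 2:
            summary["venn"]["total"] = cistrans.overlap_degs(deg_tables)
            summary["venn"]["total_direction_aware"] = cistrans.overlap_degs(
                deg_tables, direction_aware=True
            )
            summary["venn"]["trans"] = cistrans.overlap_degs(trans_tables)
            summary["venn"]["trans_direction_aware"] = cistrans.overlap_degs(
                trans_tables, direction_aware=True
            )

        stage = "compensation"
        summary["compensation"] = {}
        for g in aneuploids:
            reduced = karyotypes[g].reduced_vs(karyotypes[euploid])
            reduced = {c for c in reduced if karyotypes[g].copies[c] == 1}
            for chrom in sorted(reduced):
                calls = compensation.classify_chromosome(
                    expr, genes, samples, test=g, reference=euploid,
                    chromosome=chrom, alpha=config.alpha,
                )
                _write(calls, f"compensation_{g}_{chrom}.tsv")
                tab = compensation.compensation_crosstab(calls)
                summary["compensation"][f"{g}:{chrom}"] = tab.to_dict()

        stage = "summary"
        summary_path = out_dir / "summary.json"
        with open(summary_path, "w") as fh:
            json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
        written.append(summary_path)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
    return _jsonable(summary)
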