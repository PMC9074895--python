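"""End-to-end orchestration: simulate -> tail call -> annotate -> TE -> model.

One :class:`~tailscape.synthio.SynthConfig` drives the whole chain; every
stage writes its declared output files into ``outdir`` and returns its
in-memory results for downstream stages and for scoring against the
planted truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import endannot, io, synthio, tailcall, temodel, tequant

__all__ = ["run_all"]


def run_all(
    config: synthio.SynthConfig,
    outdir,
    n_tags: int = 100_000,
    n_standard_tags: int = 2000,
    n_coordinate_tags: int = 100_000,
    n_boot: int = 50,
    write_trace_file: bool = True,
) -> dict:
    """Run the full synthetic pipeline, writing all declared outputs.

    Returns a dict of the stage results (transcriptome, tag truth, tail
    calls, per-gene mean tails, 3'-end annotations, TE table, model fit).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- simulate ---------------------------------------------------------
    txome = synthio.make_transcriptome(config)
    txome.write_fasta(outdir / "transcriptome.fa")
    txome.write_gtf(outdir / "transcriptome.gtf")
    raw, tag_truth = synthio.simulate_intensity_tags(
        config, txome, n_tags=n_tags, n_standard_tags=n_standard_tags
    )
    tag_truth.drop(columns="read2_seq").to_csv(
        outdir / "tag_truth.tsv", sep="\t", index=False
    )
    if write_trace_file:
        io.write_traces(
            outdir / "intensity_traces.tsv.gz", raw, tag_truth["tag_id"]
        )

    # --- tail calling -----------------------------------------------------
    result = tailcall.call_tails(
        raw,
        tag_truth["read2_seq"],
        tag_truth["tag_id"],
        tag_truth["gene"],
        np.asarray(config.channel_norms),
        seed=config.seed,
    )
    result.calls.to_csv(outdir / "tail_calls.tsv", sep="\t", index=False)
    io.write_params(outdir / "ghmm_trained.json", result.params)
    mrna_calls = result.calls[~result.calls["gene"].astype(str).str.startswith("std_")]
    gene_tails = tailcall.aggregate_gene_tails(mrna_calls, min_tags=50)
    gene_tails.rename("mean_tail").to_csv(outdir / "gene_mean_tails.tsv", sep="\t")
    std_calls = result.calls[result.calls["gene"].astype(str).str.startswith("std_")]
    standards = tailcall.standards_report(
        std_calls,
        {
            f"std_{length}": (length, frac)
            for length, frac in config.standards
        },
    )
    standards.to_csv(outdir / "standards_report.tsv", sep="\t", index=False)

    # --- 3'-end annotation ------------------------------------------------
    tag_coords = synthio.simulate_tag_coordinates(config, txome, n_tags=n_coordinate_tags)
    tag_coords.to_csv(outdir / "tag_coordinates.tsv", sep="\t", index=False)
    ends = endannot.annotate_all_genes(tag_coords)
    ends.to_csv(outdir / "three_prime_ends.tsv", sep="\t", index=False)
    endannot.write_ends_bed(ends, outdir / "three_prime_ends.bed")

    # --- TE quantification ------------------------------------------------
    features, folding = synthio.make_feature_inputs(config, txome)
    rna, rpf, te_true = synthio.simulate_counts(config, features)
    pd.DataFrame({"rna": rna, "rpf": rpf}).to_csv(outdir / "counts.tsv", sep="\t")
    te_table = tequant.compute_te(rpf, rna)
    te_table.to_csv(outdir / "te_table.tsv", sep="\t")

    # --- TE model ---------------------------------------------------------
    iso = txome.isoforms.copy()
    iso["expression"] = (
        txome.gene_table.loc[iso["gene"], "expression_weight"].to_numpy()
        * iso["fraction"].to_numpy()
    )
    iso["fe_per_nt"] = folding.loc[iso["gene"], "fe_utr3_per_nt"].to_numpy()
    table = temodel.build_feature_table(
        txome.sequences,
        mean_tail=gene_tails.reindex(txome.sequences.index).fillna(
            txome.gene_table["tail_mean_true"]
        ),
        expression=te_table["rna_rpm"].reindex(txome.sequences.index).fillna(
            txome.gene_table["expression_weight"]
        ),
        folding=folding,
        isoform_utr3=iso,
    )
    model_genes = te_table.index.intersection(table.simple.dropna().index)
    table = temodel.FeatureTable(
        simple=table.simple.loc[model_genes],
        complexes=[
            temodel.ComplexFeature(c.name, c.matrix.loc[model_genes], c.ridge_alpha)
            for c in table.complexes
        ],
    )
    te = te_table.loc[model_genes, "te"]
    design = temodel.assemble_design(table, te, cross_fit=5)
    round1 = temodel.stepwise_select(design, te)
    round2 = temodel.filter_and_refit(design, te, round1)
    fit = temodel.evaluate_model(table, te, round2["round2"], n_boot=n_boot, seed=config.seed)
    (outdir / "model_fit.json").write_text(
        json.dumps(
            {
                "features": fit.features,
                "heldout_r2_mean": fit.heldout_r2_mean,
                "heldout_r2_ci": list(fit.heldout_r2_ci),
                "cumulative_r2_mean": fit.cumulative_r2_mean.tolist(),
                "cumulative_r2_ci": fit.cumulative_r2_ci.tolist(),
                "standalone_r2": fit.standalone_r2.to_dict(),
                "signs": fit.signs.to_dict(),
                "training_r2_mean": fit.training_r2_mean,
                "round1": round1,
            },
            indent=1,
        )
    )
    pd.DataFrame(
        {
            "feature": fit.features,
            "cumulative_r2": fit.cumulative_r2_mean,
            "ci_lo": fit.cumulative_r2_ci[:, 0],
            "ci_hi": fit.cumulative_r2_ci[:, 1],
            "standalone_r2": fit.standalone_r2.to_numpy(),
        }
    ).to_csv(outdir / "model_steps.tsv", sep="\t", index=False)
    fit.correlations.to_csv(outdir / "feature_correlations.tsv", sep="\t")

    return {
        "transcriptome": txome,
        "tag_truth": tag_truth,
        "calls": result.calls,
        "trained_params": result.params,
        "gene_tails": gene_tails,
        "standards": standards,
        "ends": ends,
        "te_table": te_table,
        "te_true": te_true,
        "model_fit": fit,
        "round1": round1,
        "round2": round2,
    }
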