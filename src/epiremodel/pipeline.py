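"""File-level stage runners tying the library together for the CLI.

Each stage reads the plain-text outputs of earlier stages from a working
directory (the layout `simulate` writes), runs the corresponding library
code, and writes BED/TSV/JSON results back.  The functions are thin; all
science lives in the library modules.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import biomarker as bm
from . import chip, enrichment, lrer, methylome, mirna, simulate, states
from .intervals import IntervalSet
from .io import (
    SampleSheet,
    read_bed,
    read_gene_models,
    read_matrix,
    write_bed,
    write_gene_models,
    write_json_report,
    write_matrix,
)

log = logging.getLogger("epiremodel")


def run_simulate(out_dir: str | Path, seed: int, config: dict | None = None) -> None:
    """Generate every pipeline input plus the ground-truth manifest."""
    cfg = config or {}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = simulate.make_genome(seed=seed)
    truth = simulate.make_truth(genome, seed=seed + 1)
    samples = simulate.default_sample_sheet()
    samples.write(out / "samples.tsv")
    write_bed(genome.islands, out / "cpg_islands.bed")
    write_gene_models(genome.genes, out / "genes.tsv")
    for factor, sites in genome.tfbs.items():
        write_bed(sites, out / f"tfbs_{factor}.bed")

    counts = simulate.simulate_mbd_counts(
        genome, samples, truth,
        depth=float(cfg.get("depth", 30.0)),
        dispersion=float(cfg.get("dispersion", 0.05)),
        seed=seed + 2,
    )
    write_matrix(counts, out / "mbd_counts.tsv")

    chip_samples = simulate.chip_sample_sheet()
    chip_samples.write(out / "chip_samples.tsv")
    chip_windows, chip_counts = simulate.simulate_chip_counts(
        genome, chip_samples, truth, seed=seed + 3
    )
    for mark, mat in chip_counts.items():
        write_matrix(mat, out / f"chip_{mark}.tsv")

    expr = simulate.simulate_expression(genome, chip_samples, truth,
                                        seed=seed + 4)
    write_matrix(expr, out / "expression.tsv")

    layout = simulate.make_probe_layout(genome, seed=seed + 5)
    betas, beta_sheet = simulate.simulate_beta_matrix(layout, truth,
                                                      seed=seed + 6)
    write_matrix(betas, out / "betas.tsv")
    beta_sheet.write(out / "beta_samples.tsv")
    write_bed(IntervalSet(list(layout.probes), list(layout.probe_ids)),
              out / "probes.bed")

    ct, controls = simulate.simulate_ct_table(truth, seed=seed + 7)
    write_matrix(ct, out / "mirna_ct.tsv")
    (out / "mirna_controls.txt").write_text("\n".join(controls) + "\n")

    write_json_report(_truth_manifest(truth), out / "truth.json")
    log.info("simulated inputs in %s", out)


def _truth_manifest(truth: simulate.SimulationTruth) -> dict:
    return {
        "dmrs": [
            {"interval": str(iv), "direction": d, "effect": e}
            for iv, d, e in truth.dmrs
        ],
        "lrea_blocks": [
            {"interval": str(b["interval"]), "genes": b["genes"]}
            for b in truth.lrea_blocks
        ],
        "lres_blocks": [
            {"interval": str(b["interval"]), "genes": b["genes"]}
            for b in truth.lres_blocks
        ],
        "de_genes": truth.de_genes,
        "tumour_markers": [str(iv) for iv in truth.tumour_markers],
        "basal_markers": [str(iv) for iv in truth.basal_markers],
        "spread_probes": truth.spread_probes,
        "mirna_folds": truth.mirna_folds,
    }


def run_assayable(work_dir: str | Path, tag_threshold: int = 18,
                  min_dist: int = 300) -> methylome.AssayableLoci:
    work = Path(work_dir)
    counts = read_matrix(work / "mbd_counts.tsv")
    windows = methylome.parse_window_index(counts.index)
    loci = methylome.call_assayable_loci(
        windows, counts["SssI"].to_numpy(),
        min_dist=min_dist, tag_threshold=tag_threshold,
    )
    write_bed(loci.loci, work / "assayable_loci.bed")
    write_json_report(
        {"n_assayable_loci": len(loci),
         "masked_bases": loci.loci.total_bases()},
        work / "assayable.json",
    )
    return loci


def run_dmr(work_dir: str | Path, alpha: float = 0.05) -> list:
    work = Path(work_dir)
    counts = read_matrix(work / "mbd_counts.tsv")
    windows = methylome.parse_window_index(counts.index)
    samples = SampleSheet.read(work / "samples.tsv")
    loci_set = read_bed(work / "assayable_loci.bed")
    loci = methylome.AssayableLoci(loci_set, counts.loc[
        [str(iv) for iv in loci_set], "SssI"].to_numpy())
    locus_counts = methylome.count_in_loci(
        counts.drop(columns=["SssI"]), windows, loci
    )
    results = methylome.call_dmrs(locus_counts, samples, alpha=alpha)
    methylome.dmr_table(results).to_csv(work / "dmrs.tsv", sep="\t",
                                        index=False)
    stable = methylome.stable_dmrs(results)
    write_bed(
        IntervalSet([r.interval for r in stable],
                    [r.direction for r in stable]),
        work / "dmrs_stable.bed",
    )
    write_json_report(methylome.dmr_summary(results), work / "dmrs.json")
    return results


def run_chip_domains(work_dir: str | Path, alpha: float = 0.05) -> dict:
    work = Path(work_dir)
    samples = SampleSheet.read(work / "chip_samples.tsv")
    summary = {}
    for mark in simulate.MARKS:
        mat = read_matrix(work / f"chip_{mark}.tsv")
        windows = methylome.parse_window_index(mat.index)
        mode = "narrow" if mark == "H3K4me3" else "broad"
        params = chip.NARROW_PARAMS if mode == "narrow" else {
            k: v for k, v in chip.BROAD_PARAMS.items() if k != "fdr"
        }
        per_cond = {}
        for cond in ("HMEC", "vHMEC"):
            pooled = mat[samples.ids(condition=cond)].sum(axis=1).to_numpy()
            regions = chip.call_enriched_regions(
                windows, pooled, mark, mode, **params
            )
            per_cond[cond] = regions
            write_bed(IntervalSet([r.interval for r in regions]),
                      work / f"regions_{mark}_{cond}.bed")
        union = chip.call_enriched_regions(
            windows, mat[samples.ids()].sum(axis=1).to_numpy(), mark, mode,
            **params,
        )
        tiles = chip.tile_regions(union) if mode == "broad" else [
            chip.TileStat(r.interval, i) for i, r in enumerate(union)
        ]
        tiles = chip.differential_tiles(tiles, windows, mat, samples, alpha)
        blocks = chip.merge_significant_tiles(tiles, mark)
        write_bed(
            IntervalSet([b.interval for b in blocks],
                        [f"{b.direction}:{b.combined_p:.3g}" for b in blocks]),
            work / f"blocks_{mark}.bed",
        )
        summary[mark] = {
            "regions_HMEC": len(per_cond["HMEC"]),
            "regions_vHMEC": len(per_cond["vHMEC"]),
            "differential_blocks": len(blocks),
        }
    write_json_report(summary, work / "chip_domains.json")
    return summary


def run_states(work_dir: str | Path) -> dict:
    work = Path(work_dir)
    summary = {}
    for cond in ("HMEC", "vHMEC"):
        mark_regions = {
            mark: read_bed(work / f"regions_{mark}_{cond}.bed")
            for mark in states.CLASSIFYING_MARKS
        }
        annos = states.segment_genome(mark_regions, cond)
        write_bed(
            IntervalSet([a.interval for a in annos],
                        [a.state for a in annos]),
            work / f"states_{cond}.bed",
        )
        counts = {}
        for a in annos:
            counts[a.state] = counts.get(a.state, 0) + 1
        summary[cond] = {"n_segments": len(annos), "by_state": counts}
    write_json_report(summary, work / "states.json")
    return summary


def run_lrer(work_dir: str | Path) -> dict:
    work = Path(work_dir)
    genes = read_gene_models(work / "genes.tsv")
    samples = SampleSheet.read(work / "chip_samples.tsv")
    expr = read_matrix(work / "expression.tsv")
    k9 = read_matrix(work / "chip_H3K9ac.tsv")
    k27 = read_matrix(work / "chip_H3K27me3.tsv")
    profiles = lrer.compute_gene_stats(
        expr,
        methylome.parse_window_index(k9.index), k9,
        methylome.parse_window_index(k27.index), k27,
        genes, samples,
    )
    regions = lrer.call_lrer(profiles)
    lrer.lrer_table(regions).to_csv(work / "lrer.tsv", sep="\t", index=False)
    write_bed(IntervalSet([r.interval for r in regions],
                          [r.name for r in regions]),
              work / "lrer.bed")
    summary = lrer.summarize_lrer(regions)
    write_json_report(summary, work / "lrer.json")
    return summary


def run_enrich(work_dir: str | Path, n_perm: int = 1000, seed: int = 0) -> None:
    work = Path(work_dir)
    dmrs = read_bed(work / "dmrs_stable.bed")
    universe = read_bed(work / "assayable_loci.bed")
    genes = read_gene_models(work / "genes.tsv")
    features = {"cpg_islands": read_bed(work / "cpg_islands.bed")}
    from .intervals import GenomicInterval

    features["promoters"] = IntervalSet([
        GenomicInterval(g.interval.chrom, max(0, g.tss - 2000), g.tss + 2000)
        for g in genes
    ])
    for bed in sorted(work.glob("tfbs_*.bed")):
        features[bed.stem] = read_bed(bed)
    records = enrichment.feature_enrichment(dmrs, features, universe,
                                            n_perm=n_perm, seed=seed)
    enrichment.enrichment_table(records).to_csv(
        work / "feature_enrichment.tsv", sep="\t", index=False
    )


def run_biomarker(work_dir: str | Path, seed: int = 0) -> list:
    work = Path(work_dir)
    betas = read_matrix(work / "betas.tsv")
    sheet = SampleSheet.read(work / "beta_samples.tsv")
    probe_bed = read_bed(work / "probes.bed")
    probe_ids = probe_bed.labels or [str(iv) for iv in probe_bed]
    candidates_bed = work / "dmrs_stable.bed"
    regions_src = read_bed(candidates_bed) if candidates_bed.exists() \
        else read_bed(work / "cpg_islands.bed")
    regions = []
    for iv in regions_src:
        member = bm.probes_in_region(probe_ids, probe_bed, iv)
        if member:
            regions.append((iv, member))
    cands = bm.roc_select(betas, sheet, regions, seed=seed)
    rows = [{
        "chrom": c.region.chrom, "start": c.region.start, "end": c.region.end,
        "train_auc": c.train_auc, "test_auc": c.test_auc,
        "n_probes": len(c.probes), "comparison": c.comparison,
    } for c in cands]
    pd.DataFrame(rows).to_csv(work / "biomarkers.tsv", sep="\t", index=False)
    write_json_report({"n_candidates": len(cands)}, work / "biomarkers.json")
    return cands


def run_mirna(work_dir: str | Path, alpha: float = 0.05) -> pd.DataFrame:
    work = Path(work_dir)
    ct = read_matrix(work / "mirna_ct.tsv")
    controls = [
        line.strip()
        for line in (work / "mirna_controls.txt").read_text().splitlines()
        if line.strip()
    ]
    kept = mirna.filter_expressed(ct, controls)
    donors = {s: s.split("_")[0] for s in ct.columns}
    conds = {s: s.split("_", 1)[1] for s in ct.columns}
    res = mirna.differential_mirna(kept, controls, donors, conds, alpha)
    res.to_csv(work / "mirna_results.tsv", sep="\t")
    write_json_report({
        "n_tested": int(res.shape[0]),
        "n_significant": int(res["significant"].sum()),
        "n_silenced": int((res["significant"] & (res["fold"] < 1)).sum()),
    }, work / "mirna.json")
    return res
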