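"""End-to-end orchestration: diversity -> SFS tests -> HKA -> scans -> MK.

Produces table-shaped TSVs per stage plus a JSON manifest recording inputs,
seeds, replicate counts and runtimes so every numeric output is traceable.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__, hka, mk, sfs, sweep
from .alignio import (
    POOLED,
    classify_sites,
    read_annotation,
    read_fasta_alignment,
    read_population_map,
)
from .coalescent import SimConfig, harmonic
from .diversity import per_gene_summaries, sliding_window_pi
from .sweep import DEFAULT_GRID, DEFAULT_MAXWIN, DEFAULT_MINWIN


@dataclass
class RunConfig:
    """Inputs and replicate settings for one pipeline run.

    Default replicate counts follow standard practice for these tests
    (50,000 for Tajima's D, 10,000 for Fay-Wu H and scan cutoffs); they
    dominate runtime and can be lowered for exploratory runs.
    """

    fasta: str
    gff: str
    populations: str
    outgroup_id: str = "outgroup"
    population: str = POOLED       # one population label, or pooled
    focal_gene: str | None = None  # default: lowest silent diversity
    d_replicates: int = 50_000
    h_replicates: int = 10_000
    cutoff_replicates: int = 10_000
    grid: int = DEFAULT_GRID
    minwin: float = DEFAULT_MINWIN
    maxwin: float = DEFAULT_MAXWIN
    window: int = 150
    step: int = 25
    rho_null: float = 50.0
    seed: int | None = None
    outdir: str = "popsweep_out"


def _sha1(path: str) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    os.makedirs(config.outdir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {p: _sha1(getattr(config, a))
                   for a, p in [("fasta", "fasta"), ("gff", "gff"),
                                ("populations", "populations")]},
        "stages": {},
    }

    aln_full = read_fasta_alignment(config.fasta, outgroup_id=config.outgroup_id)
    annotations = read_annotation(config.gff)
    pmap = read_population_map(config.populations)
    pmap.validate_against(aln_full)
    if config.population == POOLED:
        aln = aln_full
    else:
        samples = pmap.samples(config.population)
        if not samples:
            raise ValueError(f"no samples in population {config.population!r}")
        aln = aln_full.subset(samples)
    classmap = classify_sites(aln, annotations)

    # --- stage 1: diversity -------------------------------------------------
    t0 = time.time()
    summaries = per_gene_summaries(aln, classmap, annotations)
    div_rows = [s.as_row() for s in summaries.values()]
    pd.DataFrame(div_rows).to_csv(
        os.path.join(config.outdir, "diversity.tsv"), sep="\t", index=False)
    track = sliding_window_pi(aln, config.window, config.step)
    track.to_bed(os.path.join(config.outdir, "window_pi.bed"))
    manifest["stages"]["diversity"] = {
        "runtime_s": round(time.time() - t0, 2),
        "windows": len(track.windows),
    }
    focal = config.focal_gene or min(
        summaries, key=lambda g: np.inf if summaries[g].pi_si is None
        else summaries[g].pi_si)

    # --- stage 2: SFS neutrality tests --------------------------------------
    t0 = time.time()
    from .alignio import polymorphism_classes
    poly_all = polymorphism_classes(aln, classmap)
    neut_rows = []
    for ann in annotations:
        span = np.zeros(classmap.L, dtype=bool)
        span[ann.start - aln.region_offset: ann.end - aln.region_offset + 1] = True
        s = summaries[ann.gene_id]
        spectrum = sfs.build_sfs(aln, columns=span & ~classmap.masked)
        d_val = sfs.tajimas_d(
            sfs.pi_from_counts(
                _silent_counts(aln, classmap, span, poly_all), aln.n),
            s.S_silent, aln.n) if s.S_silent else None
        h_val = sfs.fay_wu_h_norm(spectrum)
        row = {"locus": ann.gene_id, "n": aln.n, "S_silent": s.S_silent,
               "D_taj": d_val, "H_fw": h_val}
        if d_val is not None:
            res = sfs.neutrality_test("D", d_val, aln.n, s.S_silent,
                                      config.d_replicates,
                                      int(rng.integers(2**31 - 1)))
            row.update(D_p=res.p_value, D_reps=res.replicates)
        if h_val is not None and s.S_silent:
            res = sfs.neutrality_test("H", h_val, aln.n, s.S_silent,
                                      config.h_replicates,
                                      int(rng.integers(2**31 - 1)))
            row.update(H_p=res.p_value, H_reps=res.replicates)
        neut_rows.append(row)
    pd.DataFrame(neut_rows).to_csv(
        os.path.join(config.outdir, "neutrality.tsv"), sep="\t", index=False)
    manifest["stages"]["neutrality"] = {"runtime_s": round(time.time() - t0, 2)}

    # --- stage 3: HKA -------------------------------------------------------
    t0 = time.time()
    loci = hka.region_hka_data(aln, classmap, annotations)
    by_id = {l.locus: l for l in loci}
    hka_rows = []
    for ann in annotations:
        if ann.gene_id == focal:
            continue
        try:
            res = hka.pairwise_hka(by_id[focal], by_id[ann.gene_id],
                                   replicates=config.cutoff_replicates,
                                   seed=int(rng.integers(2**31 - 1)))
            hka_rows.append({"locus_a": focal, "locus_b": ann.gene_id,
                             "X2": res.x2, "P": res.p_value})
        except ValueError as exc:
            hka_rows.append({"locus_a": focal, "locus_b": ann.gene_id,
                             "X2": None, "P": None, "note": str(exc)})
    pd.DataFrame(hka_rows).to_csv(
        os.path.join(config.outdir, "hka_pairwise.tsv"), sep="\t", index=False)
    fit0 = hka.mlhka_fit(loci, seed=int(rng.integers(2**31 - 1)))
    fit1 = hka.mlhka_fit(loci, focal_ids=[focal], selection=True,
                         seed=int(rng.integers(2**31 - 1)))
    lrt = hka.mlhka_lrt(fit0, fit1)
    pd.DataFrame([
        {"hypothesis": "no-selection", "k": 1.0, "L": fit0.loglik,
         "twoDeltaL": None, "P": None},
        {"hypothesis": "selection", "k": fit1.k.get(focal),
         "L": fit1.loglik, "twoDeltaL": lrt.two_delta_l, "P": lrt.p_value},
    ]).to_csv(os.path.join(config.outdir, "mlhka.tsv"), sep="\t", index=False)
    manifest["stages"]["hka"] = {"runtime_s": round(time.time() - t0, 2),
                                 "focal": focal}

    # --- stage 4: sweep scans -----------------------------------------------
    t0 = time.time()
    snps = sweep.SnpMatrix.from_alignment(aln)
    region_L = float(aln.L)
    theta_hat = snps.S / harmonic(aln.n)
    clr_track = sweep.clr_scan(snps, grid=config.grid)
    clr_cut = sweep.clr_cutoff(SimConfig(
        n=aln.n, theta=theta_hat, L=region_L,
        replicates=config.cutoff_replicates,
        seed=int(rng.integers(2**31 - 1))))
    clr_track.cutoff, clr_track.cutoff_quantile = clr_cut.cutoff, 0.99
    clr_track.replicates = config.cutoff_replicates
    clr_track.to_tsv(os.path.join(config.outdir, "clr_track.tsv"))
    om_track = sweep.omega_scan(snps, grid=config.grid,
                                minwin=config.minwin, maxwin=config.maxwin)
    om_cut = sweep.omega_cutoff(SimConfig(
        n=aln.n, theta=theta_hat, rho=config.rho_null, L=region_L,
        replicates=config.cutoff_replicates,
        seed=int(rng.integers(2**31 - 1))),
        minwin=config.minwin, maxwin=config.maxwin)
    om_track.cutoff, om_track.cutoff_quantile = om_cut.cutoff, 0.99
    om_track.replicates = config.cutoff_replicates
    om_track.to_tsv(os.path.join(config.outdir, "omega_track.tsv"))
    with open(os.path.join(config.outdir, "scan_summary.json"), "w") as fh:
        json.dump({"clr": clr_track.summary(), "omega": om_track.summary()},
                  fh, indent=2, default=float)
    manifest["stages"]["sweep_scan"] = {
        "runtime_s": round(time.time() - t0, 2),
        "clr_max": clr_track.max_value, "omega_max": om_track.max_value,
    }

    # --- stage 5: MK / dN-dS ------------------------------------------------
    t0 = time.time()
    mk_rows = []
    for ann in annotations:
        sub = _gene_classmap(aln, classmap, ann)
        table = mk.polarized_substitution_counts(aln, sub)
        try:
            res = mk.mk_test(table)
            p = res.p_value
        except ValueError:
            p = None
        try:
            dnds = mk.gene_dnds(aln, classmap, ann)
            dn, ds, ratio = dnds.dN, dnds.dS, dnds.ratio
        except ValueError:
            dn = ds = ratio = None
        mk_rows.append({"locus": ann.gene_id, "dN": dn, "dS": ds,
                        "dN_dS": ratio, "Da": table.Da, "Ds": table.Ds,
                        "Pa": table.Pa, "Ps": table.Ps, "P": p})
    pd.DataFrame(mk_rows).to_csv(
        os.path.join(config.outdir, "mk.tsv"), sep="\t", index=False)
    manifest["stages"]["mk_dnds"] = {"runtime_s": round(time.time() - t0, 2)}

    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest


def _silent_counts(aln, classmap, span, poly):
    """Minor-allele counts at silent segregating columns within a span
    (intronic columns plus coding columns with a synonymous change)."""
    from .alignio import BASES
    m = aln.ingroup_matrix
    sel = poly.loc[
        span[poly["column"].to_numpy()]
        & ((poly["label"] == "intronic") | (poly["synonymous"] == True)),
        "column"].to_numpy()
    counts = []
    for col in sel:
        cs = sorted((int(np.sum(m[:, col] == b)) for b in BASES), reverse=True)
        counts.append(cs[1])
    return np.asarray(counts, dtype=np.int64)


def _gene_classmap(aln, classmap, ann):
    """Restrict a region classmap to one gene's codons (for MK counting)."""
    import copy
    sub = copy.copy(classmap)
    keep = {cid for cid, ((c0, c1, c2), _) in classmap.codon_cols.items()
            if ann.start - aln.region_offset <= min(c0, c1, c2)
            and max(c0, c1, c2) <= ann.end - aln.region_offset}
    sub.codon_cols = {cid: v for cid, v in classmap.codon_cols.items()
                      if cid in keep}
    return sub
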