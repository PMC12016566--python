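"""Format readers and writers plus the end-to-end pipeline driver.

Conventions: VCF positions are 1-based; BED-like coverage tables are
0-based half-open; all report coordinates are printed 1-based inclusive.
Every run writes a JSON manifest recording seeds, thresholds and SHA-256
digests of the stage outputs so reruns are verifiably byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from . import expression as expr_mod
from . import lmm, oxygen, selection, svgeno
from .simulate import (
    DepthProfileSet,
    GenotypeMatrix,
    OxygenEquilibriumCurve,
    PhenotypeTable,
    SimConfig,
    simulate_deletion_cohort,
    simulate_depth_profiles,
    simulate_expression,
    simulate_genotypes,
    simulate_oxygen_curve,
)

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_phenotype_tsv",
    "read_phenotype_tsv",
    "write_depth_tsv",
    "read_depth_tsv",
    "write_oec_csv",
    "read_oec_csv",
    "run_pipeline",
]


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> Path:
    """Emit a minimal VCF v4.2 with phased GT fields ('|' separators)."""
    path = Path(path)
    n = genotypes.n_samples
    haps = genotypes.haplotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = genotypes.variants["chrom"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        for j, rec in enumerate(genotypes.variants.itertuples(index=False)):
            fields = [str(rec.chrom), str(rec.pos), ".", rec.ref, rec.alt, ".", "PASS", ".", "GT"]
            for i in range(n):
                dos = genotypes.dosages[i, j]
                if dos < 0:
                    fields.append("./.")
                elif haps is not None:
                    fields.append(f"{haps[2 * i, j]}|{haps[2 * i + 1, j]}")
                else:
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}[int(dos)]
                    fields.append(gt)
            fh.write("\t".join(fields) + "\n")
    return path


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a biallelic VCF into dosages and (when phased) haplotypes.

    Multi-allelic records are skipped (count logged to the returned
    variants frame's attrs); missing genotypes become dosage -1.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosage_rows, hap_rows = [], [], []
    n_skipped = 0
    all_phased = True
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        vtype = "SNP" if len(rec.REF) == 1 and len(rec.ALT[0]) == 1 else "INDEL"
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0], vtype))
        gts = rec.genotypes  # [allele1, allele2, phased]
        dos, haps = [], []
        for g in gts:
            a1, a2 = g[0], g[1]
            if a1 < 0 or a2 < 0:
                dos.append(-1)
                haps.append((0, 0))
                all_phased = False
            else:
                dos.append(a1 + a2)
                haps.append((a1, a2))
                all_phased = all_phased and bool(g[2])
        dosage_rows.append(dos)
        hap_rows.append(haps)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "type"])
    variants.attrs["n_multiallelic_skipped"] = n_skipped
    dosages = np.array(dosage_rows, dtype=np.int8).T
    if dosages.size == 0:
        dosages = np.empty((len(samples), 0), dtype=np.int8)
    haplotypes = None
    if all_phased and hap_rows:
        h = np.array(hap_rows, dtype=np.int8)  # m x n x 2
        haplotypes = h.transpose(1, 2, 0).reshape(2 * len(samples), -1)
    return GenotypeMatrix(samples, variants, dosages, haplotypes)


def write_phenotype_tsv(phen: PhenotypeTable, path: str | Path) -> Path:
    path = Path(path)
    phen.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_phenotype_tsv(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    cov = df.drop(columns=["sample_id", "altitude_m"])
    return PhenotypeTable(
        list(df["sample_id"].astype(str)),
        df["altitude_m"].to_numpy(dtype=float),
        cov if not cov.empty else None,
    )


def write_depth_tsv(profiles: DepthProfileSet, path: str | Path) -> Path:
    """BED-like coverage table (chrom, start, end, sample, depth), 0-based half-open."""
    path = Path(path)
    profiles.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_depth_tsv(path: str | Path) -> DepthProfileSet:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    samples = list(dict.fromkeys(df["sample"]))
    first = df[df["sample"] == samples[0]].sort_values("start")
    starts = first["start"].to_numpy(dtype=np.int64)
    ends = first["end"].to_numpy(dtype=np.int64)
    depth = np.empty((len(samples), starts.size))
    for i, s in enumerate(samples):
        sub = df[df["sample"] == s].sort_values("start")
        if not (np.array_equal(sub["start"].to_numpy(), starts)):
            raise ValueError(f"sample {s} has a different window grid")
        depth[i] = sub["depth"].to_numpy(dtype=float)
    return DepthProfileSet(samples, str(first["chrom"].iloc[0]), starts, ends, depth)


def write_oec_csv(curves: list[OxygenEquilibriumCurve], path: str | Path) -> Path:
    path = Path(path)
    pd.concat([c.to_frame() for c in curves], ignore_index=True).to_csv(
        path, index=False
    )
    return path


def read_oec_csv(path: str | Path) -> list[OxygenEquilibriumCurve]:
    df = pd.read_csv(path)
    curves = []
    for (ph, t, cond), sub in df.groupby(["ph", "temp_c", "condition"], sort=False):
        curves.append(
            OxygenEquilibriumCurve(
                sub["po2_torr"].to_numpy(dtype=float),
                sub["saturation"].to_numpy(dtype=float),
                ph=float(ph),
                temp_c=float(t),
                condition=str(cond),
            )
        )
    return curves


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    out_dir: str | Path,
    seed: int = 0,
    *,
    stages: tuple[str, ...] = ("simulate", "gwas", "xpehh", "diplotype", "oxy", "expr"),
    n_samples: int = 200,
    n_variants: int = 500,
    alpha: float = 0.05,
    maf_min: float = 0.05,
) -> dict:
    """Run the requested stages end to end on a simulated cohort.

    Returns (and writes) a manifest recording the configuration, per-stage
    summary numbers and SHA-256 digests of every output file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": seed,
        "stages": list(stages),
        "alpha": alpha,
        "maf_min": maf_min,
        "outputs": {},
        "summary": {},
    }

    config = SimConfig(seed=seed, n_samples=n_samples, n_variants=n_variants)
    cohort = simulate_deletion_cohort(config)
    geno, phen = cohort.genotypes, cohort.phenotype

    if "simulate" in stages:
        f = write_vcf(geno, out / "genotypes.vcf")
        manifest["outputs"]["genotypes.vcf"] = _sha256(f)
        f = write_phenotype_tsv(phen, out / "phenotype.tsv")
        manifest["outputs"]["phenotype.tsv"] = _sha256(f)

    kinship = lmm.compute_grm(geno, maf_min=maf_min)
    if "gwas" in stages:
        pcs = lmm.pc_covariates(geno, k=3)
        res = lmm.association_scan(geno, phen.altitude, pcs, kinship, alpha,
                                   maf_min=maf_min)
        f = out / "association.tsv"
        res.table.to_csv(f, sep="\t", index=False)
        manifest["outputs"]["association.tsv"] = _sha256(f)
        manifest["summary"]["gwas"] = {
            "n_tests": res.n_tests,
            "bonferroni_p": res.bonferroni_p,
            "lambda_hat": res.lambda_hat,
            "tau_hat": res.tau_hat,
            "n_significant": int(res.table["significant"].sum()),
            "approximation": res.approximation,
        }

    if "xpehh" in stages:
        half = geno.n_samples // 2
        pos = geno.variants["pos"].to_numpy()
        focal = selection.HaplotypePanel(
            geno.haplotypes[: 2 * half], pos, geno.variants["chrom"].iloc[0], "focal"
        )
        refp = selection.HaplotypePanel(
            geno.haplotypes[2 * half :], pos, geno.variants["chrom"].iloc[0], "reference"
        )
        sites = selection.xpehh_scan(focal, refp)
        wins = selection.windowize(sites)
        lo_t, hi_t = selection.empirical_threshold(wins["stat"].to_numpy())
        f = out / "xpehh_sites.tsv"
        sites.to_csv(f, sep="\t", index=False)
        manifest["outputs"]["xpehh_sites.tsv"] = _sha256(f)
        f = out / "xpehh_windows.tsv"
        wins.to_csv(f, sep="\t", index=False)
        manifest["outputs"]["xpehh_windows.tsv"] = _sha256(f)
        manifest["summary"]["xpehh"] = {
            "n_windows": int(len(wins)),
            "threshold_low": lo_t,
            "threshold_high": hi_t,
        }

    if "diplotype" in stages:
        diplos = ["AA", "AB", "BB"][: max(3, 0)]
        counts = {"AA": 0, "AB": 0, "BB": 0}
        labels = []
        for d in cohort.a_dosage.astype(int):
            lab = {2: "AA", 1: "AB", 0: "BB"}[d]
            labels.append(lab)
            counts[lab] += 1
        profiles = simulate_depth_profiles(labels, config)
        f = write_depth_tsv(profiles, out / "coverage.tsv")
        manifest["outputs"]["coverage.tsv"] = _sha256(f)
        calls = svgeno.diplotype_table(profiles, config.deletion_interval)
        f = out / "diplotypes.tsv"
        calls.to_csv(f, sep="\t", index=False)
        manifest["outputs"]["diplotypes.tsv"] = _sha256(f)
        vc = calls["call"].value_counts()
        freq = svgeno.haplotype_frequency(
            int(vc.get("AA", 0)), int(vc.get("AB", 0)), int(vc.get("BB", 0))
        )
        manifest["summary"]["diplotype"] = {
            "constructed": counts,
            "called": {k: int(vc.get(k, 0)) for k in ("AA", "AB", "BB")},
            "haplotype_a_frequency": freq,
        }

    if "oxy" in stages:
        grid = np.array([5, 8, 12, 18, 25, 35, 50, 70, 100], dtype=float)
        curves = [
            simulate_oxygen_curve(config.hb_P50, config.hb_n50, grid, 0.0,
                                  ph=7.4, temp_c=37.0),
            simulate_oxygen_curve(config.hb_P50 * 1.4, config.hb_n50, grid, 0.0,
                                  ph=6.9, temp_c=37.0),
            simulate_oxygen_curve(config.hb_P50 * 0.75, config.hb_n50, grid, 0.0,
                                  ph=7.4, temp_c=25.0),
        ]
        f = write_oec_csv(curves, out / "oec.csv")
        manifest["outputs"]["oec.csv"] = _sha256(f)
        fits = [oxygen.fit_hill(c) for c in curves]
        phi = oxygen.bohr_factor(fits[0], fits[1])
        thermo = oxygen.vant_hoff_enthalpy(fits[0], fits[2])
        manifest["summary"]["oxy"] = {
            "P50": fits[0].P50,
            "n50": fits[0].n50,
            "bohr_factor": phi,
            "delta_H_kJ": thermo.delta_H / 1000,
            "delta_H_prime_kJ": thermo.delta_H_prime / 1000,
        }

    if "expr" in stages:
        alt = np.linspace(0, 5000, geno.n_samples)
        phen_e = PhenotypeTable(list(geno.sample_ids), alt)
        table = simulate_expression(
            200, phen_e, {"G00000": 0.4, "G00001": -0.4}, config
        )
        tpm_tab = expr_mod.tpm(table.counts, table.effective_lengths)
        f = out / "tpm.tsv"
        tpm_tab.to_csv(f, sep="\t")
        manifest["outputs"]["tpm.tsv"] = _sha256(f)
        trend = expr_mod.altitude_trend(tpm_tab, alt)
        ok = trend["testable"]
        trend.loc[ok, "q"] = expr_mod.bh_fdr(trend.loc[ok, "p"])
        f = out / "trend.tsv"
        trend.to_csv(f, sep="\t")
        manifest["outputs"]["trend.tsv"] = _sha256(f)
        manifest["summary"]["expr"] = {
            "n_trend_q_lt_0.05": int((trend["q"].dropna() < 0.05).sum())
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
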