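"""Reading and writing of genotype, map and phenotype tables.

Genotypes come in as VCF (biallelic, GT only) or as a TSV allele matrix and
are validated into the 0/2 homozygous coding. Heterozygous or missing calls
are a hard error by default: the pipeline expects imputed fully homozygous
input. All writers emit deterministic, tab-separated UTF-8 text with '.'
for NA (legal only in phenotypes), so write -> read round-trips exactly.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import GenotypePanel, MarkerMap, PhenotypeTable, ValidationError


# ---------------------------------------------------------------------------
# Genotypes


def read_genotypes(path, format: str = "auto", allow_het: bool = False,
                   populations: dict[str, str] | None = None) -> GenotypePanel:
    path = Path(path)
    if format == "auto":
        format = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "tsv"
    if format == "vcf":
        return _read_vcf(path, allow_het, populations)
    if format == "tsv":
        return _read_geno_tsv(path, allow_het, populations)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path, allow_het: bool, populations) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, map_rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValidationError(
                f"multi-allelic site {var.CHROM}:{var.POS} (ALT={var.ALT}); "
                "only biallelic records are supported"
            )
        gts = np.asarray(var.gt_types)  # 0=hom_ref 1=het 2=unknown 3=hom_alt
        if not allow_het and np.any((gts == 1) | (gts == 2)):
            bad = samples[int(np.flatnonzero((gts == 1) | (gts == 2))[0])]
            raise ValidationError(
                f"heterozygous/missing call at {var.CHROM}:{var.POS} (sample {bad}); "
                "DH input must be homozygous - pass allow_het=True to mean-round"
            )
        col = np.where(gts == 3, 2, 0).astype(np.int8)
        if allow_het and np.any((gts == 1) | (gts == 2)):
            # mean-rounding override: round the site mean dosage to 0 or 2
            known = col[(gts == 0) | (gts == 3)]
            fill = 2 if (known.mean() if len(known) else 0) >= 1 else 0
            col = np.where((gts == 1) | (gts == 2), fill, col).astype(np.int8)
        rows.append(col)
        map_rows.append({"marker": var.ID or f"{var.CHROM}_{var.POS}",
                         "chrom": var.CHROM, "pos_bp": var.POS})
    geno = np.column_stack(rows)
    marker_map = MarkerMap(pd.DataFrame(map_rows))
    pops = [populations.get(s, "unknown") if populations else "unknown" for s in samples]
    return GenotypePanel(samples, pops, geno, marker_map)


def _read_geno_tsv(path: Path, allow_het: bool, populations) -> GenotypePanel:
    """TSV matrix: columns line, population, then one column per marker."""
    df = pd.read_csv(path, sep="\t", dtype={"line": str})
    if "line" not in df.columns:
        raise ValidationError("genotype TSV needs a 'line' column")
    lines = df["line"].tolist()
    pops = df["population"].tolist() if "population" in df.columns else ["unknown"] * len(lines)
    if populations:
        pops = [populations.get(l, p) for l, p in zip(lines, pops)]
    marker_cols = [c for c in df.columns if c not in ("line", "population")]
    geno = df[marker_cols].to_numpy()
    if np.isin(geno, 1).any() and not allow_het:
        i, j = np.argwhere(geno == 1)[0]
        raise ValidationError(
            f"heterozygous value 1 for line {lines[i]}, marker {marker_cols[j]}"
        )
    if allow_het:
        G = geno.astype(float)
        for j in range(G.shape[1]):
            het = G[:, j] == 1
            if het.any():
                G[het, j] = 2.0 if G[~het, j].mean() >= 1 else 0.0
        geno = G
    marker_map = _map_from_marker_names(marker_cols)
    return GenotypePanel(lines, pops, geno.astype(np.int8), marker_map)


def _map_from_marker_names(names: list[str]) -> MarkerMap:
    """Markers named <chrom>:<pos_bp>[:<cM>] carry their own map."""
    rows = []
    for k, name in enumerate(names):
        parts = name.split(":")
        if len(parts) >= 2:
            rows.append({"marker": name, "chrom": parts[0], "pos_bp": int(parts[1]),
                         **({"pos_cM": float(parts[2])} if len(parts) > 2 else {})})
        else:
            rows.append({"marker": name, "chrom": "chr0", "pos_bp": k + 1})
    return MarkerMap(pd.DataFrame(rows))


def write_genotypes_tsv(panel: GenotypePanel, path) -> None:
    t = panel.marker_map.table
    names = [
        f"{c}:{p}" + (f":{cm:.6f}" if "pos_cM" in t.columns else "")
        for c, p, cm in zip(t["chrom"], t["pos_bp"],
                            t["pos_cM"] if "pos_cM" in t.columns else t["pos_bp"])
    ]
    df = pd.DataFrame(panel.geno, columns=names)
    df.insert(0, "population", panel.populations)
    df.insert(0, "line", panel.lines)
    df.to_csv(path, sep="\t", index=False)


def write_genotypes_vcf(panel: GenotypePanel, path) -> None:
    """Minimal VCF 4.2 with GT only; 0/0 and 1/1 calls (REF=A, ALT=T placeholders)."""
    t = panel.marker_map.table
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in t["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.lines) + "\n")
        for j, row in enumerate(t.itertuples(index=False)):
            calls = "\t".join("1/1" if g == 2 else "0/0" for g in panel.geno[:, j])
            fh.write(f"{row.chrom}\t{row.pos_bp}\t{row.marker}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


# ---------------------------------------------------------------------------
# Marker map / phenotypes


def read_marker_map(path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t", na_values=["."])
    rename = {"chromosome": "chrom", "position": "pos_bp", "bp": "pos_bp", "cM": "pos_cM"}
    df = df.rename(columns={k: v for k, v in rename.items() if k in df.columns})
    sorted_in = df.sort_values(["chrom", "pos_bp"], kind="mergesort").reset_index(drop=True)
    if not sorted_in[["chrom", "pos_bp"]].equals(
        df[["chrom", "pos_bp"]].reset_index(drop=True)
    ):
        warnings.warn("marker map rows were not sorted; sorting by (chrom, bp)")
    return MarkerMap(df)


def write_marker_map(marker_map: MarkerMap, path) -> None:
    marker_map.table.to_csv(path, sep="\t", index=False, na_rep=".")


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", na_values=["."], dtype={"line": str})
    missing = {"line", "environment", "trait", "value"} - set(df.columns)
    if missing:
        raise ValidationError(f"phenotype TSV missing columns: {sorted(missing)}")
    df = df.dropna(subset=["value"])
    return PhenotypeTable(df[["line", "environment", "trait", "value"]])


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.table.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.10g")


# ---------------------------------------------------------------------------
# Result bundles


def write_results(tables: dict[str, pd.DataFrame], out_dir, meta: dict | None = None) -> dict:
    """Write named TSVs plus a JSON manifest (file hashes, row counts, metadata).

    Re-running with identical inputs reproduces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}, "meta": meta or {}}
    for name, df in tables.items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, na_rep=".", float_format="%.10g")
        manifest["files"][name] = {
            "path": p.name,
            "rows": int(len(df)),
            "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
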