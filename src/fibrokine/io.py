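"""Readers and writers for the external text formats the pipeline touches.

A dataset bundle is a directory holding a Matrix Market sparse matrix with
``features.tsv`` / ``barcodes.tsv`` sidecars (10x-style, matrix stored
features x barcodes), optionally spot coordinates (``coords.tsv``: barcode,
array_row, array_col), a BED peak file with a GC column, and a
``manifest.json`` with provenance (package version, seed, config hash) and
file checksums.  Readers validate rather than coerce: dimension mismatches,
duplicate barcodes and non-integer counts are rejected with specific error
codes.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp

from ._utils import file_checksum
from .bulk import GeneSignature
from .motifs import PeakMatrix
from .scoring import ExpressionMatrix


class FormatError(ValueError):
    """Malformed input file; ``code`` identifies the rule violated."""

    def __init__(self, code: str, message: str):
        super().__init__(f"[{code}] {message}")
        self.code = code


def _provenance(seed=None, config_hash=None) -> dict:
    from . import __version__

    return {"package": "fibrokine", "version": __version__, "seed": seed,
            "config_hash": config_hash}


def write_mtx_bundle(
    em: ExpressionMatrix,
    outdir: str | Path,
    seed: int | None = None,
    config_hash: str | None = None,
) -> Path:
    """Write an expression matrix as mtx + features/barcodes (+ coords) bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(em.values).T  # stored features x barcodes
    spio.mmwrite(str(outdir / "matrix.mtx"), mat, field="integer" if em.kind == "counts" else "real")
    pd.Series(list(em.gene_ids)).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(list(em.obs.index)).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    files = ["matrix.mtx", "features.tsv", "barcodes.tsv"]
    if {"array_row", "array_col"}.issubset(em.obs.columns):
        em.obs[["array_row", "array_col"]].rename_axis("barcode").to_csv(
            outdir / "coords.tsv", sep="\t"
        )
        files.append("coords.tsv")
    obs_cols = [c for c in em.obs.columns if c not in ("array_row", "array_col")]
    if obs_cols:
        em.obs[obs_cols].rename_axis("barcode").to_csv(outdir / "obs.tsv", sep="\t")
        files.append("obs.tsv")
    manifest = _provenance(seed, config_hash)
    manifest["kind"] = em.kind
    manifest["scale_factor"] = em.scale_factor
    manifest["checksums"] = {f: file_checksum(outdir / f) for f in files}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def read_mtx_bundle(indir: str | Path, expect_counts: bool = True) -> ExpressionMatrix:
    """Read a bundle back into an observations x genes ExpressionMatrix.

    Orientation is auto-detected from the sidecar lengths: whichever header
    dimension matches the features sidecar is treated as the gene axis.  A
    square matrix with equal sidecar lengths is assumed features x barcodes.
    """
    indir = Path(indir)
    for f in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (indir / f).exists():
            raise FileNotFoundError(indir / f)
    mat = sp.csr_matrix(spio.mmread(str(indir / "matrix.mtx")))
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    if barcodes.duplicated().any():
        dups = list(barcodes[barcodes.duplicated()][:3])
        raise FormatError("duplicate_barcode", f"duplicate barcodes {dups}")

    nr, nc = mat.shape
    if nr == len(features) and nc == len(barcodes):
        mat = mat.T.tocsr()  # features x barcodes dialect
    elif nr == len(barcodes) and nc == len(features):
        pass
    else:
        raise FormatError(
            "dim_mismatch",
            f"matrix {mat.shape} inconsistent with {len(features)} features / "
            f"{len(barcodes)} barcodes",
        )

    kind = "counts"
    scale = None
    manifest_path = indir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        kind = manifest.get("kind", "counts")
        scale = manifest.get("scale_factor")
    if expect_counts and kind == "counts":
        if mat.data.size and np.any(mat.data != np.round(mat.data)):
            raise FormatError("non_integer", "count matrix holds non-integer values")
        mat = mat.astype(np.int64)

    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    coords_path = indir / "coords.tsv"
    if coords_path.exists():
        coords = pd.read_csv(coords_path, sep="\t", index_col="barcode")
        if not coords.index.equals(obs.index):
            raise FormatError("dim_mismatch", "coords barcodes differ from matrix barcodes")
        obs = obs.join(coords)
    obs_path = indir / "obs.tsv"
    if obs_path.exists():
        extra = pd.read_csv(obs_path, sep="\t", index_col="barcode")
        extra.index = extra.index.astype(str)
        obs = obs.join(extra)
    return ExpressionMatrix(
        values=mat, obs=obs, gene_ids=pd.Index(features), kind=kind, scale_factor=scale
    )


# ---------------------------------------------------------------------------
# BED peaks
# ---------------------------------------------------------------------------


def write_bed_peaks(pm: PeakMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = pm.peak_coords.copy()
    df["gc"] = pm.gc
    df.to_csv(path, sep="\t", header=False, index=False)
    return path


def read_bed_peaks(path: str | Path) -> pd.DataFrame:
    """Read a BED file (0-based half-open) with an optional 4th GC column.

    Rejects intervals with end <= start (naming the offending line) and GC
    values outside [0, 1].  Unsorted input is preserved but flagged with a
    warning.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError("bad_bed", f"line {ln}: fewer than 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise FormatError("bad_interval", f"line {ln}: end <= start ({start}, {end})")
            rec = {"chrom": chrom, "start": start, "end": end}
            if len(parts) >= 4:
                gc = float(parts[3])
                if not 0.0 <= gc <= 1.0:
                    raise FormatError("bad_gc", f"line {ln}: GC {gc} outside [0, 1]")
                rec["gc"] = gc
            rows.append(rec)
    df = pd.DataFrame(rows)
    if len(df) > 1:
        sorted_ok = df.sort_values(["chrom", "start"]).reset_index(drop=True)[["chrom", "start"]]
        if not sorted_ok.equals(df[["chrom", "start"]].reset_index(drop=True)):
            warnings.warn("BED input not coordinate-sorted; order preserved", stacklevel=2)
    return df


# ---------------------------------------------------------------------------
# peak / motif bundles
# ---------------------------------------------------------------------------


def write_peak_bundle(
    pm: PeakMatrix, mm, outdir: str | Path, seed: int | None = None
) -> Path:
    """Write a binary accessibility bundle: matrix, barcodes, BED peaks, motifs."""
    from .motifs import MotifMatch  # local import to avoid cycles at module load

    assert isinstance(mm, MotifMatch)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(outdir / "peaks.mtx"), sp.coo_matrix(pm.binary), field="integer")
    pd.Series([f"cell_{i:05d}" for i in range(pm.n_cells)]).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    write_bed_peaks(pm, outdir / "peaks.bed")
    spio.mmwrite(str(outdir / "motif_match.mtx"), sp.coo_matrix(mm.match), field="integer")
    pd.DataFrame(
        {
            "motif": mm.motif_names,
            "tfs": [",".join(mm.motif_to_tf[m]) for m in mm.motif_names],
        }
    ).to_csv(outdir / "motifs.tsv", sep="\t", index=False)
    files = ["peaks.mtx", "barcodes.tsv", "peaks.bed", "motif_match.mtx", "motifs.tsv"]
    manifest = _provenance(seed)
    manifest["checksums"] = {f: file_checksum(outdir / f) for f in files}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def read_peak_bundle(indir: str | Path):
    """Read a peak bundle back into (PeakMatrix, MotifMatch)."""
    from .motifs import MotifMatch

    indir = Path(indir)
    mat = sp.csr_matrix(spio.mmread(str(indir / "peaks.mtx")))
    if mat.data.size and np.any((mat.data != 0) & (mat.data != 1)):
        raise FormatError("non_binary", "peak matrix must be binarised")
    bed = read_bed_peaks(indir / "peaks.bed")
    if "gc" not in bed.columns:
        raise FormatError("bad_bed", "peak BED must carry a GC column")
    if len(bed) != mat.shape[0]:
        raise FormatError("dim_mismatch", "BED rows differ from matrix peak rows")
    pm = PeakMatrix(binary=mat, peak_coords=bed[["chrom", "start", "end"]], gc=bed["gc"].to_numpy())
    motifs = pd.read_csv(indir / "motifs.tsv", sep="\t")
    match = sp.csr_matrix(spio.mmread(str(indir / "motif_match.mtx")))
    if match.shape[1] != mat.shape[0]:
        raise FormatError("dim_mismatch", "motif match columns differ from peaks")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mm = MotifMatch(
            match=match,
            motif_names=list(motifs["motif"].astype(str)),
            motif_to_tf={
                str(r.motif): str(r.tfs).split(",") for r in motifs.itertuples()
            },
        )
    return pm, mm


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------


def write_signature_file(sig: GeneSignature, path: str | Path) -> Path:
    path = Path(path)
    rows = [{"gene": g, "direction": "up"} for g in sorted(sig.up)] + [
        {"gene": g, "direction": "down"} for g in sorted(sig.down)
    ]
    with open(path, "w") as fh:
        fh.write(f"# signature: {sig.name}\n")
        fh.write(f"# provenance: {sig.provenance}\n")
        pd.DataFrame(rows, columns=["gene", "direction"]).to_csv(fh, sep="\t", index=False)
    return path


def read_signature_file(path: str | Path, name: str | None = None) -> GeneSignature:
    """Delimited-text signature: columns ``gene`` and ``direction`` in {up, down}."""
    path = Path(path)
    sig_name = name or path.stem
    header_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line)
            else:
                break
    for line in header_lines:
        if line.startswith("# signature:") and name is None:
            sig_name = line.split(":", 1)[1].strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    if len(df) == 0:
        warnings.warn(f"empty signature file {path}", stacklevel=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return GeneSignature(name=sig_name, up=set(), down=set())
    if not {"gene", "direction"}.issubset(df.columns):
        raise FormatError("bad_signature", "need columns gene, direction")
    bad = set(df["direction"]) - {"up", "down"}
    if bad:
        raise FormatError("bad_direction", f"unknown direction token(s) {sorted(bad)}")
    per_gene = df.groupby("gene")["direction"].nunique()
    conflict = list(per_gene.index[per_gene > 1])
    if conflict:
        raise FormatError("conflicting_direction", f"gene(s) in both directions: {conflict[:5]}")
    up = set(df.loc[df["direction"] == "up", "gene"].astype(str))
    down = set(df.loc[df["direction"] == "down", "gene"].astype(str))
    return GeneSignature(name=sig_name, up=up, down=down, provenance=f"read from {path.name}")


# ---------------------------------------------------------------------------
# small tables
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path, seed=None, config_hash=None) -> Path:
    """Write a result table with a provenance comment header."""
    path = Path(path)
    prov = _provenance(seed, config_hash)
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(prov)}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
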