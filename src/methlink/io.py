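"""Readers and writers for every on-disk format the pipeline touches.

Conventions: tabular data is TSV (header row, UTF-8, ``.`` for missing);
interval tracks are BED (0-based half-open, label in column 4); matrices
carry their id column first (``probe_id`` / ``gene_id``).  Every writer's
output round-trips through the matching reader.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, IntervalTrack

logger = logging.getLogger(__name__)

NA_REP = "."

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_bed",
    "write_bed",
    "read_gene_models",
    "write_gene_models",
    "read_sample_sheet",
    "read_manifest",
    "load_dataset",
    "write_results",
    "write_run_manifest",
]


def read_matrix(path, index_name: str = "probe_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_REP], keep_default_na=True)
    df.index.name = index_name
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep=NA_REP, float_format="%.10g")


def read_bed(path, kind: str = "generic") -> IntervalTrack:
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], parts[1], parts[2]
            try:
                start, end = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            label = parts[3] if len(parts) > 3 else "."
            entries.append((chrom, start, end, label))
    return IntervalTrack(entries, kind=kind)


def write_bed(track: IntervalTrack, path) -> None:
    track.df.to_csv(path, sep="\t", header=False, index=False)


_GENE_COLUMNS = [
    "gene_id",
    "chrom",
    "strand",
    "tx_start",
    "tx_end",
    "first_exon_start",
    "first_exon_end",
    "utr5_start",
    "utr5_end",
    "utr3_start",
    "utr3_end",
]


def write_gene_models(genes, path) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "tx_start": g.tx_start,
                "tx_end": g.tx_end,
                "first_exon_start": g.first_exon[0],
                "first_exon_end": g.first_exon[1],
                "utr5_start": g.utr5[0] if g.utr5 else NA_REP,
                "utr5_end": g.utr5[1] if g.utr5 else NA_REP,
                "utr3_start": g.utr3[0] if g.utr3 else NA_REP,
                "utr3_end": g.utr3[1] if g.utr3 else NA_REP,
            }
        )
    pd.DataFrame(rows, columns=_GENE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_models(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP])
    genes = []
    for _, r in df.iterrows():
        def _iv(a, b):
            if pd.isna(r[a]) or pd.isna(r[b]):
                return None
            return (int(r[a]), int(r[b]))

        genes.append(
            GeneModel(
                gene_id=str(r["gene_id"]),
                chrom=str(r["chrom"]),
                strand=str(r["strand"]),
                tx_start=int(r["tx_start"]),
                tx_end=int(r["tx_end"]),
                first_exon=_iv("first_exon_start", "first_exon_end"),
                utr5=_iv("utr5_start", "utr5_end"),
                utr3=_iv("utr3_start", "utr3_end"),
            )
        )
    return genes


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", index_col="sample")
    required = {"subject", "group", "cell_stage"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet


def read_manifest(path) -> pd.DataFrame:
    man = pd.read_csv(path, sep="\t", index_col="probe_id")
    required = {"chrom", "pos"}
    missing = required - set(man.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return man


def load_dataset(
    beta_path,
    sample_sheet_path,
    manifest_path,
    detection_p_path=None,
) -> dict:
    """Load and cross-validate the core study files.

    Sample ids must agree between the beta matrix (and detection matrix)
    and the sample sheet; probe ids must be present in the manifest.
    Mismatches fail with the offending ids named.
    """
    beta = read_matrix(beta_path)
    sheet = read_sample_sheet(sample_sheet_path)
    manifest = read_manifest(manifest_path)

    unknown_samples = [s for s in beta.columns if s not in sheet.index]
    if unknown_samples:
        raise ValueError(f"samples absent from sample sheet: {unknown_samples[:5]}")
    unknown_probes = beta.index.difference(manifest.index)
    if len(unknown_probes):
        raise ValueError(f"probes absent from manifest: {list(unknown_probes[:5])}")

    out = {"beta": beta, "sample_sheet": sheet, "manifest": manifest}
    if detection_p_path is not None:
        det = read_matrix(detection_p_path)
        if not det.index.equals(beta.index) or list(det.columns) != list(beta.columns):
            raise ValueError("detection-p matrix shape/ids do not match beta matrix")
        out["detection_p"] = det
    logger.info(
        "loaded dataset: %d probes x %d samples", beta.shape[0], beta.shape[1]
    )
    return out


def _sort_result_table(df: pd.DataFrame) -> pd.DataFrame:
    by = [c for c in ("q", "p") if c in df.columns]
    out = df.sort_values(by + [df.index.name or "index"], kind="mergesort") if by else df.sort_index()
    return out


def write_results(outdir, tables: dict[str, pd.DataFrame], metadata: dict | None = None) -> dict[str, Path]:
    """Write result tables under ``outdir`` with deterministic ordering.

    Tables with ``q``/``p`` columns are sorted by (q, p, id); others by id.
    Empty tables still produce a header-only file.  A run-manifest JSON is
    written alongside when ``metadata`` is given.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = outdir / f"{name}.tsv"
        out = _sort_result_table(df) if len(df) else df
        out.to_csv(path, sep="\t", na_rep=NA_REP, float_format="%.10g")
        paths[name] = path
    if metadata is not None:
        paths["run_manifest"] = write_run_manifest(outdir / "run_manifest.json", metadata, paths)
    return paths


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_run_manifest(path, metadata: dict, output_paths: dict | None = None) -> Path:
    """Record config, seed, versions and output checksums for reproducibility."""
    meta = dict(metadata)
    if is_dataclass(meta.get("config")):
        meta["config"] = asdict(meta["config"])
    meta.setdefault("versions", {})
    meta["versions"].update(
        {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }
    )
    if output_paths:
        meta["output_checksums"] = {
            name: _checksum(p) for name, p in sorted(output_paths.items()) if Path(p).is_file()
        }
    path = Path(path)
    path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
    return path


def write_study(study, outdir) -> dict[str, Path]:
    """Write every object of a synthetic study in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _save(name, fn):
        paths[name] = outdir / name
        fn(paths[name])

    _save("sample_sheet.tsv", lambda p: study.sample_sheet.to_csv(p, sep="\t"))
    _save("manifest.tsv", lambda p: study.manifest.to_csv(p, sep="\t"))
    _save("genes.tsv", lambda p: write_gene_models(study.genes, p))
    _save("cgi.bed", lambda p: write_bed(study.cgi, p))
    _save("chromatin.bed", lambda p: write_bed(study.chromatin, p))
    _save("tfbs.bed", lambda p: write_bed(study.tfbs, p))
    for stage, bdf in study.beta.items():
        _save(f"beta_{stage}.tsv", lambda p, b=bdf: write_matrix(b, p))
        _save(
            f"detection_p_{stage}.tsv",
            lambda p, d=study.detection_p[stage]: write_matrix(d, p),
        )
    _save("expression.tsv", lambda p: write_matrix(study.expression, p))
    _save("ct_table.tsv", lambda p: study.ct_table.to_csv(p, sep="\t", index=False))
    _save(
        "truth_dmcpg.tsv", lambda p: study.truth.planted_dm.to_csv(p, sep="\t")
    )
    _save("truth_deg.tsv", lambda p: study.truth.planted_deg.to_csv(p, sep="\t"))
    paths["run_manifest.json"] = write_run_manifest(
        outdir / "run_manifest.json",
        {"config": study.config, "seed": study.config.seed},
        {k: v for k, v in paths.items()},
    )
    return paths
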