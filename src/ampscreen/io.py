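"""Readers and writers for every file format the pipeline touches.

Sequence data move through standard FASTA/FASTQ (Biopython); tabular data
are plain CSV/TSV with headers; fitted models and run reports are JSON.
Every writer/reader pair round-trips its in-memory structure exactly.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError
from .genotyping import LocusSpec, OutcomeTable
from .size_bias import BiasModel, CalibrationPool


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def write_fastq(reads: list[tuple[str, str]], path) -> None:
    """Write (read_id, sequence) pairs as FASTQ with uniform quality."""
    records = []
    for read_id, seq in reads:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> list[tuple[str, str]]:
    """Read merged reads from FASTQ; qualities are parsed but unused."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTQ not found: {path}")
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fastq")]


def write_locus(locus: LocusSpec, fasta_path, tsv_path) -> None:
    """Write a locus as reference FASTA plus a cut-site TSV sidecar."""
    SeqIO.write([SeqRecord(Seq(locus.reference_seq), id=locus.name,
                           description="")], str(fasta_path), "fasta")
    with open(tsv_path, "w") as fh:
        fh.write("name\tcut_sites\tsgrna_seqs\n")
        fh.write(f"{locus.name}\t"
                 f"{','.join(str(c) for c in locus.cut_sites)}\t"
                 f"{','.join(locus.sgrna_seqs)}\n")


def read_locus(fasta_path, tsv_path) -> LocusSpec:
    """Read a locus from its FASTA + TSV sidecar pair."""
    for p in (fasta_path, tsv_path):
        if not Path(p).exists():
            raise InputError(f"locus file not found: {p}")
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise InputError(f"{fasta_path}: expected exactly one reference record")
    meta = pd.read_csv(tsv_path, sep="\t", dtype=str).fillna("")
    if "cut_sites" not in meta.columns or len(meta) != 1:
        raise InputError(f"{tsv_path}: expected one row with a cut_sites column")
    row = meta.iloc[0]
    name = row.get("name") or records[0].id
    cuts = tuple(int(x) for x in str(row["cut_sites"]).split(","))
    sgrnas = tuple(s for s in str(row.get("sgrna_seqs", "")).split(",") if s)
    return LocusSpec(name, str(records[0].seq).upper(), cuts, sgrnas)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def merge_read_pair(r1: str, r2: str, min_overlap: int = 20,
                    min_identity: float = 0.9) -> str | None:
    """Naive overlap merger for simulated paired reads.

    ``r2`` is reverse-complemented and slid along ``r1``; the overlap with
    the most matches (>= ``min_overlap`` long, >= ``min_identity`` matching)
    wins. Returns None when no acceptable overlap exists. Only intended for
    simulator output — real data should be merged upstream by a dedicated
    tool.
    """
    r2rc = r2.translate(_COMPLEMENT)[::-1]
    best = None
    for overlap in range(min(len(r1), len(r2rc)), min_overlap - 1, -1):
        a, b = r1[-overlap:], r2rc[:overlap]
        matches = sum(x == y for x, y in zip(a, b))
        if matches / overlap >= min_identity:
            score = matches
            if best is None or score > best[0]:
                best = (score, overlap)
    if best is None:
        return None
    _, overlap = best
    return r1 + r2rc[overlap:]


# ---------------------------------------------------------------------------
# Calibration pools and bias models
# ---------------------------------------------------------------------------

POOL_COLUMNS = ["pool_id", "fragment_id", "length_bp", "starting_fraction",
                "read_count", "is_reference"]


def write_pools_csv(pools: list[CalibrationPool], path,
                    depth: int = 1_000_000) -> None:
    """Write calibration pools; measured fractions become read counts."""
    rows = []
    for pool in pools:
        for i, (length, s, m) in enumerate(zip(pool.fragment_lengths,
                                               pool.starting_fractions,
                                               pool.measured_fractions)):
            rows.append((pool.pool_id, f"frag_{length}bp", length, s,
                         m * depth, i == pool.reference_index))
    pd.DataFrame(rows, columns=POOL_COLUMNS).to_csv(path, index=False)


def read_pools_csv(path) -> list[CalibrationPool]:
    """Read calibration pools from CSV (one reference fragment per pool)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"pool CSV not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in POOL_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    pools = []
    for pool_id, sub in df.groupby("pool_id", sort=False):
        refs = sub.index[sub["is_reference"].astype(bool)].tolist()
        if len(refs) != 1:
            raise InputError(f"pool {pool_id!r}: need exactly one reference "
                             "fragment")
        sub = sub.reset_index(drop=True)
        ref_idx = int(sub.index[sub["is_reference"].astype(bool)][0])
        pools.append(CalibrationPool.from_counts(
            sub["length_bp"].tolist(), sub["starting_fraction"].tolist(),
            sub["read_count"].tolist(), ref_idx, str(pool_id)))
    return pools


def write_bias_model(model: BiasModel, path) -> None:
    with open(path, "w") as fh:
        json.dump({"slope_log2_per_bp": model.slope_log2_per_bp,
                   "intercept_log2": model.intercept_log2,
                   "n_points": model.n_points,
                   "r_squared": model.r_squared}, fh, indent=2)
        fh.write("\n")


def read_bias_model(path) -> BiasModel:
    path = Path(path)
    if not path.exists():
        raise InputError(f"bias model JSON not found: {path}")
    with open(path) as fh:
        d = json.load(fh)
    try:
        return BiasModel(float(d["slope_log2_per_bp"]),
                         float(d.get("intercept_log2", 0.0)),
                         int(d.get("n_points", 0)),
                         float(d.get("r_squared", float("nan"))))
    except (KeyError, TypeError, ValueError) as exc:
        raise InputError(f"{path}: malformed bias model: {exc}") from exc


# ---------------------------------------------------------------------------
# Genotyping outputs
# ---------------------------------------------------------------------------

def write_outcome_tsv(table: OutcomeTable, path) -> None:
    """Per-outcome TSV: outcome_key, category, length, raw and corrected counts."""
    table.outcomes.to_csv(path, sep="\t", index=False)


def write_sample_summary_tsv(summaries: pd.DataFrame, path) -> None:
    """Per-sample summary TSV (sample, on-target reads, efficiency, filter)."""
    cols = ["sample", "on_target_corrected", "efficiency_pct", "passes_filter"]
    missing = [c for c in cols if c not in summaries.columns]
    if missing:
        raise InputError(f"summary table missing columns {missing}")
    summaries[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Screen tables
# ---------------------------------------------------------------------------

def _read_csv(path, required: list[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"{what} CSV not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    return df


def read_layout_csv(path) -> pd.DataFrame:
    from .screen import LAYOUT_COLUMNS
    df = _read_csv(path, LAYOUT_COLUMNS, "layout")
    df["gene"] = df["gene"].fillna("")
    return df


def read_measurements_csv(path) -> pd.DataFrame:
    from .screen import MEASUREMENT_COLUMNS
    return _read_csv(path, MEASUREMENT_COLUMNS, "measurements")


def read_luminescence_csv(path) -> pd.DataFrame:
    from .screen import LUMINESCENCE_COLUMNS
    return _read_csv(path, LUMINESCENCE_COLUMNS, "luminescence")


def read_standards_csv(path) -> pd.DataFrame:
    return _read_csv(path, ["concentration_pg_ml", "absorbance"], "standards")


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)
        fh.write("\n")


def provenance(seed=None, config: dict | None = None) -> dict:
    """Machine-readable provenance block for run reports."""
    import numpy
    import ampscreen
    return {
        "package": "ampscreen",
        "version": ampscreen.__version__,
        "python": platform.python_version(),
        "numpy": numpy.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "config": config or {},
    }
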