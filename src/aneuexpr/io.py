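"""Readers, writers and run configuration.

All tabular formats are plain TSV (UTF-8, '.' decimal, no quoting);
gene annotation can also travel as GFF3 with ``type=gene`` features
carrying ``ID``, ``exonic_length`` and ``subgenome`` attributes.
Floats are written with Python repr precision so every table
round-trips bit-exactly through its own reader.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .models import Karyotype, validate_genes
from .simulate import SimConfig, SimTruth

__all__ = [
    "read_counts",
    "write_counts",
    "read_annotation",
    "write_annotation_tsv",
    "write_annotation_gff3",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_karyotypes",
    "write_karyotypes",
    "write_truth",
    "read_truth",
    "read_flat_config",
    "sim_config_from_file",
    "RunConfig",
]


# ---------------------------------------------------------------- counts

def read_counts(path) -> pd.DataFrame:
    """Gene x sample integer count matrix from TSV.

    First column holds gene ids; remaining columns are samples.
    Duplicate gene ids, ragged rows and non-integer cells are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        line = int(np.flatnonzero(df.index == dup)[-1]) + 2  # +1 header, +1 1-based
        raise ValueError(f"duplicate gene id {dup!r} (line {line}) in {path}")
    if df.isna().any().any():
        raise ValueError(f"missing cells in count matrix {path}")
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.integer):
            as_float = vals.astype(float)
            if not np.all(as_float == np.floor(as_float)):
                bad = vals.index[as_float != np.floor(as_float)][0]
                raise ValueError(f"non-integer count for gene {bad!r}, sample {col!r}")
            df[col] = as_float.astype(np.int64)
    if (df.to_numpy() < 0).any():
        raise ValueError("negative counts are not allowed")
    df.index.name = "gene_id"
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    out = counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ------------------------------------------------------------ annotation

_GENE_TSV_COLS = ["gene_id", "chromosome", "start", "end", "exonic_length", "subgenome"]


def _is_gff(path: Path) -> bool:
    if path.suffix.lower() in (".gff", ".gff3"):
        return True
    with open(path) as fh:
        first = fh.readline()
    return first.startswith("##gff-version")


def read_annotation(path) -> pd.DataFrame:
    """Gene annotation from GFF3 or flat TSV.

    Missing ``exonic_length`` falls back to the genomic span with a
    warning; both encodings of the same genes parse identically.
    """
    path = Path(path)
    if _is_gff(path):
        genes = _read_annotation_gff3(path)
    else:
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in _GENE_TSV_COLS[:4] if c not in df.columns]
        if missing:
            raise ValueError(f"annotation TSV missing columns: {missing}")
        if "exonic_length" not in df.columns or df["exonic_length"].isna().any():
            warnings.warn("exonic_length missing; falling back to genomic span", stacklevel=2)
            span = df["end"] - df["start"] + 1
            df["exonic_length"] = df.get("exonic_length", pd.Series(np.nan, index=df.index))
            df["exonic_length"] = df["exonic_length"].fillna(span)
        if "subgenome" not in df.columns:
            df["subgenome"] = df["chromosome"].str[0]
        genes = df.set_index("gene_id")[
            ["chromosome", "start", "end", "exonic_length", "subgenome"]
        ]
    genes = genes.astype(
        {"start": np.int64, "end": np.int64, "exonic_length": np.int64}
    )
    return validate_genes(genes)


def _read_annotation_gff3(path: Path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    rows = []
    for feat in db.features_of_type("gene"):
        if feat.id is None or feat.id.startswith("unnamed"):
            raise ValueError(f"gene feature without ID at {feat.seqid}:{feat.start}")
        attrs = feat.attributes
        if "exonic_length" in attrs:
            length = int(attrs["exonic_length"][0])
        else:
            warnings.warn(
                f"gene {feat.id}: exonic_length missing; using genomic span", stacklevel=3
            )
            length = feat.end - feat.start + 1
        sub = attrs["subgenome"][0] if "subgenome" in attrs else feat.seqid[0]
        rows.append(
            {
                "gene_id": feat.id,
                "chromosome": feat.seqid,
                "start": feat.start,
                "end": feat.end,
                "exonic_length": length,
                "subgenome": sub,
            }
        )
    if not rows:
        raise ValueError(f"no gene features in {path}")
    return pd.DataFrame(rows).set_index("gene_id")


def write_annotation_tsv(genes: pd.DataFrame, path) -> None:
    out = genes.reset_index()
    out.columns = ["gene_id"] + list(out.columns[1:])
    out.to_csv(path, sep="\t", index=False)


def write_annotation_gff3(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, row in genes.iterrows():
            attrs = (
                f"ID={gid};exonic_length={int(row.exonic_length)};"
                f"subgenome={row.subgenome}"
            )
            fh.write(
                f"{row.chromosome}\taneuexpr\tgene\t{int(row.start)}\t{int(row.end)}"
                f"\t.\t+\t.\t{attrs}\n"
            )


# ----------------------------------------------------------- sample sheet

def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = ["sample_id", "group", "replicate"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r}")
    return df[needed]


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- karyotypes

def read_karyotypes(path) -> dict:
    """TSV with columns group, chromosome, copies -> {group: Karyotype}."""
    df = pd.read_csv(path, sep="\t")
    needed = ["group", "chromosome", "copies"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"karyotype file missing columns: {missing}")
    out = {}
    for group, sub in df.groupby("group", sort=False):
        if sub["chromosome"].duplicated().any():
            raise ValueError(f"duplicate chromosome in karyotype of {group!r}")
        out[group] = Karyotype(group, dict(zip(sub["chromosome"], sub["copies"].astype(int))))
    return out


def write_karyotypes(karyotypes: dict, path) -> None:
    rows = [
        {"group": g, "chromosome": c, "copies": n}
        for g, k in karyotypes.items()
        for c, n in sorted(k.copies.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ truth

def write_truth(truth: SimTruth, out_dir) -> None:
    """Write the simulator's ground truth as a directory of TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_karyotypes(truth.karyotypes, out / "truth_karyotypes.tsv")
    mf = truth.mean_factor.copy()
    mf.index.name = "gene_id"
    mf.to_csv(out / "truth_mean_factor.tsv", sep="\t")
    mc = truth.mean_counts.copy()
    mc.index.name = "gene_id"
    mc.to_csv(out / "truth_mean_counts.tsv", sep="\t")
    long = []
    for g in truth.trans_lfc.columns:
        flagged = truth.is_trans.index[truth.is_trans[g]]
        long.append(
            pd.DataFrame(
                {"gene_id": flagged, "group": g, "log2fc": truth.trans_lfc.loc[flagged, g]}
            )
        )
    trans = (
        pd.concat(long, ignore_index=True)
        if long
        else pd.DataFrame(columns=["gene_id", "group", "log2fc"])
    )
    trans.to_csv(out / "truth_trans.tsv", sep="\t", index=False)
    truth.compensation.to_csv(out / "truth_compensation.tsv", sep="\t", index=False)


def read_truth(truth_dir) -> SimTruth:
    """Rebuild a :class:`SimTruth` from :func:`write_truth` output."""
    d = Path(truth_dir)
    karyotypes = read_karyotypes(d / "truth_karyotypes.tsv")
    mean_factor = pd.read_csv(d / "truth_mean_factor.tsv", sep="\t", index_col=0)
    mean_counts = pd.read_csv(d / "truth_mean_counts.tsv", sep="\t", index_col=0)
    trans = pd.read_csv(d / "truth_trans.tsv", sep="\t")
    trans_lfc = pd.DataFrame(0.0, index=mean_factor.index, columns=mean_factor.columns)
    is_trans = pd.DataFrame(False, index=mean_factor.index, columns=mean_factor.columns)
    for row in trans.itertuples():
        trans_lfc.loc[row.gene_id, row.group] = row.log2fc
        is_trans.loc[row.gene_id, row.group] = True
    comp = pd.read_csv(d / "truth_compensation.tsv", sep="\t")
    return SimTruth(
        karyotypes=karyotypes,
        mean_factor=mean_factor,
        mean_counts=mean_counts,
        trans_lfc=trans_lfc,
        is_trans=is_trans,
        compensation=comp,
    )


# ----------------------------------------------------------- configuration

def read_flat_config(path) -> dict:
    """Flat ``key = value`` config file; '#' starts a comment."""
    out = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key in out:
                raise ValueError(f"{path}:{lineno}: duplicate key {key!r}")
            out[key] = value
    return out


_SIM_SCALAR_FIELDS = {
    f.name: f.type
    for f in fields(SimConfig)
    if f.name not in ("dosage_multipliers", "karyotypes", "compensation_mix",
                      "compensated_factor_range", "anti_factor_range")
}


def sim_config_from_file(path) -> SimConfig:
    """Build a :class:`SimConfig` from a flat key-value file.

    Scalar fields only; ``compensation_mix`` may be given as three
    comma-separated proportions.  Unknown keys are errors.
    """
    raw = read_flat_config(path)
    kwargs = {}
    for key, value in raw.items():
        if key == "compensation_mix":
            kwargs[key] = tuple(float(v) for v in value.split(","))
        elif key in _SIM_SCALAR_FIELDS:
            default = getattr(SimConfig, key)
            kwargs[key] = type(default)(float(value)) if isinstance(default, (int, float)) else value
        else:
            raise ValueError(f"unknown simulation config key {key!r}")
    return SimConfig(**kwargs)


@dataclass
class RunConfig:
    """Paths, thresholds and seed for a full pipeline run."""

    counts: str
    annotation: str
    samples: str
    karyotypes: str
    out_dir: str
    fc_threshold: float = 2.0
    q_threshold: float = 0.05
    alpha: float = 0.05
    min_genes: int = 10
    bin_edges: tuple = (0.1, 10.0, 100.0)
    seed: int = 0

    def __post_init__(self):
        for name in ("fc_threshold", "q_threshold", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        e = self.bin_edges
        if len(e) != 3 or not (e[0] < e[1] < e[2]):
            raise ValueError("bin_edges must be strictly increasing")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = read_flat_config(path)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown run config key(s): {sorted(unknown)}")
        kwargs = {}
        for key, value in raw.items():
            if key in ("counts", "annotation", "samples", "karyotypes", "out_dir"):
                kwargs[key] = value
            elif key == "bin_edges":
                kwargs[key] = tuple(float(v) for v in value.split(","))
            elif key in ("min_genes", "seed"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)
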