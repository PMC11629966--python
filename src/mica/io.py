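"""Reading study tables, writing result tables, and flat config files.

Expression tables are delimited text (TSV by default, CSV for ``.csv``
paths), genes in rows with the gene identifier in the first column and a
header row of sample identifiers. The metadata table maps every sample to a
study and a class. Gene universes are intersected across studies and rows
are canonicalized to sorted gene-id order. Missing values are an error:
inputs are assumed already normalized and filtered upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_stats import StudyData

__all__ = [
    "DatasetBundle",
    "ValidationError",
    "read_studies",
    "bundle_from_frames",
    "write_results",
    "read_results",
    "parse_config",
    "write_dataset",
]

#: serialization used for unavailable values in result tables
NA_TOKEN = "NA"
#: significant digits for floats in result tables
FLOAT_DIGITS = 6


class ValidationError(ValueError):
    """Aggregated input-validation failure."""


@dataclass(eq=False)
class DatasetBundle:
    """Validated multi-study dataset sharing one gene universe."""

    studies: list[StudyData]
    gene_ids: pd.Index
    metadata: pd.DataFrame

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def study_ids(self) -> list[str]:
        return [s.study for s in self.studies]


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _read_table(path, transpose: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    if transpose:
        df = df.T
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(converted.isna().to_numpy())
        if bad.size:
            raise ValidationError(
                f"{path}: malformed numeric cell at row {df.index[bad[0]]!r} "
                f"(line {bad[0] + 2}), column {col!r} (column {j + 2}): "
                f"{df.iloc[bad[0], j]!r}"
            )
        values[col] = converted
    return values


def bundle_from_frames(
    tables: Mapping[str, pd.DataFrame], metadata: pd.DataFrame
) -> DatasetBundle:
    """Validate per-study genes-x-samples frames against sample metadata."""
    errors: list[str] = []
    meta = metadata.copy()
    required = {"sample", "study", "class"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValidationError(
            f"metadata is missing column(s): {', '.join(sorted(missing_cols))}"
        )
    meta["sample"] = meta["sample"].astype(str)
    meta["study"] = meta["study"].astype(str)
    if meta["sample"].duplicated().any():
        dup = meta.loc[meta["sample"].duplicated(), "sample"].iloc[0]
        errors.append(f"metadata: sample {dup!r} appears more than once")
    meta = meta.set_index("sample")

    class_sets = {}
    studies_raw = {}
    for study_id, df in tables.items():
        study_id = str(study_id)
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            errors.append(f"study {study_id!r}: duplicate gene id {dup!r}")
        unknown = [c for c in df.columns if str(c) not in meta.index]
        if unknown:
            errors.append(
                f"study {study_id!r}: sample(s) missing from metadata: "
                f"{', '.join(map(str, unknown[:5]))}"
            )
            continue
        sub = meta.loc[[str(c) for c in df.columns]]
        wrong = sub[sub["study"] != study_id]
        if len(wrong):
            errors.append(
                f"study {study_id!r}: sample {wrong.index[0]!r} is assigned to "
                f"study {wrong['study'].iloc[0]!r} in the metadata"
            )
        class_sets[study_id] = set(sub["class"])
        studies_raw[study_id] = (df, sub["class"].to_numpy())

    if class_sets:
        all_classes = sorted(set.union(*class_sets.values()))
        for study_id, cs in class_sets.items():
            for c in sorted(set(all_classes) - cs):
                errors.append(f"study {study_id!r}: class {c!r} has no samples")
    if errors:
        raise ValidationError("; ".join(errors))

    common = None
    for study_id, (df, _) in studies_raw.items():
        common = set(df.index) if common is None else common & set(df.index)
    if not common:
        raise ValidationError("no genes shared across all studies")
    gene_ids = pd.Index(sorted(common), name="gene_id")
    dropped = {sid: len(df.index) - len(gene_ids) for sid, (df, _) in studies_raw.items()}
    if any(dropped.values()):
        warnings.warn(
            "genes dropped by cross-study intersection: "
            + ", ".join(f"{sid}: {n}" for sid, n in dropped.items() if n),
            stacklevel=2,
        )

    studies = []
    for study_id, (df, classes) in studies_raw.items():
        vals = df.loc[gene_ids].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            g, i = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"study {study_id!r}: missing/non-finite value at gene "
                f"{gene_ids[g]!r}, sample {df.columns[i]!r}"
            )
        studies.append(StudyData(values=vals, labels=classes, study=study_id))
    return DatasetBundle(studies=studies, gene_ids=gene_ids, metadata=metadata)


def read_studies(
    paths: Sequence, metadata_path, transpose: bool = False
) -> DatasetBundle:
    """Read per-study expression tables plus a sample-metadata table.

    ``paths`` are delimited text files (genes x samples unless
    ``transpose``); the study id is the file stem unless the metadata maps
    its samples to a single study id. Metadata columns: ``sample``,
    ``study``, ``class``.
    """
    from pathlib import Path

    meta = pd.read_csv(metadata_path, sep=_sep_for(metadata_path), dtype=str)
    tables = {}
    for p in paths:
        df = _read_table(p, transpose=transpose)
        stem = Path(str(p)).stem
        if "sample" in meta.columns and "study" in meta.columns:
            hit = meta[meta["sample"].astype(str).isin([str(c) for c in df.columns])]
            ids = set(hit["study"].astype(str))
            study_id = ids.pop() if len(ids) == 1 else stem
        else:
            study_id = stem
        if study_id in tables:
            raise ValidationError(f"duplicate study id {study_id!r}")
        tables[study_id] = df
    return bundle_from_frames(tables, meta)


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return NA_TOKEN
    if isinstance(v, (float, np.floating)):
        return f"{v:.{FLOAT_DIGITS}g}"
    return str(v)


def write_results(results, path) -> None:
    """Write a per-gene results table as TSV.

    Columns: ``gene_id``, the stage-1 statistic (``gmi_plus`` or
    ``min_mcc``), ``p_value``, ``q_value``, one ``posthoc_p_<i>_<j>`` column
    per study pair, ``concordant_subsets`` (``;``-separated subsets, studies
    joined by ``+``) and ``module_label``. Floats carry 6 significant
    digits; unavailable post hoc entries are ``NA``.
    """
    df = results.to_frame() if hasattr(results, "to_frame") else results
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(_fmt)
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN)


def read_results(path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False)
    for col in ("concordant_subsets", "module_label"):
        if col in df.columns:
            df[col] = df[col].fillna("").astype(str)
    return df


def write_dataset(studies, truth, out_dir) -> dict[str, str]:
    """Write simulated studies + metadata + truth as TSV files.

    Returns the mapping of logical names to file paths.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    meta_rows = []
    gene_ids = truth["gene_id"].tolist()
    for s in studies:
        cols = [f"s{s.study}_{i + 1:03d}" for i in range(s.n_samples)]
        df = pd.DataFrame(np.atleast_2d(s.values), index=gene_ids, columns=cols)
        df.index.name = "gene_id"
        p = out / f"study_{s.study}.tsv"
        df.to_csv(p, sep="\t", float_format=f"%.{FLOAT_DIGITS}g")
        paths[f"study_{s.study}"] = str(p)
        meta_rows += [
            {"sample": c, "study": s.study, "class": lab}
            for c, lab in zip(cols, s.labels)
        ]
    mp = out / "metadata.tsv"
    pd.DataFrame(meta_rows).to_csv(mp, sep="\t", index=False)
    paths["metadata"] = str(mp)
    tp = out / "truth.tsv"
    truth.to_csv(tp, sep="\t", index=False)
    paths["truth"] = str(tp)
    return paths


_CONFIG_KEYS = {
    "studies": ("n_studies", int),
    "n_studies": ("n_studies", int),
    "classes": ("n_classes", int),
    "n_classes": ("n_classes", int),
    "n_per_class": ("n_per_class", int),
    "rho_mean": ("rho_mean", float),
    "tau": ("tau", float),
    "noise_sd": ("noise_sd", float),
    "replicates": ("n_replicates", int),
    "n_replicates": ("n_replicates", int),
    "permutations": ("n_permutations", int),
    "n_permutations": ("n_permutations", int),
    "seed": ("seed", int),
}


def parse_config(path):
    """Parse a flat ``key = value`` simulation config file.

    Recognized keys mirror :class:`~mica.simulation.SimulationConfig`
    fields; ``genes_type_i`` .. ``genes_type_iv`` set the per-type gene
    counts. Blank lines and ``#`` comments are ignored.
    """
    from .simulation import SimulationConfig

    kwargs = {}
    genes = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (part.strip() for part in line.split("=", 1))
            key = key.lower()
            if key.startswith("genes_type_"):
                genes[key.removeprefix("genes_type_").upper()] = int(val)
            elif key in _CONFIG_KEYS:
                field_name, cast = _CONFIG_KEYS[key]
                kwargs[field_name] = cast(val)
            else:
                raise ValidationError(f"{path}:{lineno}: unknown key {key!r}")
    if genes:
        kwargs["genes_per_type"] = genes
    return SimulationConfig(**kwargs)
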