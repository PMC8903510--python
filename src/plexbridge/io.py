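"""Tab-separated readers/writers for PSM tables, designs, matrices, clinical tables.

All tables are plain TSV. The PSM schema is one row per PSM::

    plex  run  spectrum  peptide  charge  entry  assignment  contaminant
    tmt_labeled  ms1_intensity  purity  probability  reporter_1..reporter_N

Empty reporter cells are read back as missing values (never 0.0). Alternative
PSM-table dialects are supported through a column-mapping dict (``colmap``)
translating dialect names to the canonical names above; unknown extra columns
are carried through untouched in ``PsmRecord.extra``.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    ClinicalAnnotation,
    DesignError,
    PlexChannel,
    PlexDesign,
    PsmRecord,
    QuantMatrix,
    SchemaError,
)

__all__ = [
    "PSM_COLUMNS",
    "read_psm_table",
    "write_psm_table",
    "read_design",
    "write_design",
    "validate_design",
    "read_matrix",
    "write_matrix",
    "read_clinical",
    "write_clinical",
    "write_manifest",
]

PSM_COLUMNS = [
    "plex",
    "run",
    "spectrum",
    "peptide",
    "charge",
    "entry",
    "assignment",
    "contaminant",
    "tmt_labeled",
    "ms1_intensity",
    "purity",
    "probability",
]


def _reporter_columns(n: int) -> list[str]:
    return [f"reporter_{i + 1}" for i in range(n)]


def read_psm_table(
    path: str | Path,
    design: PlexDesign,
    colmap: dict[str, str] | None = None,
) -> list[PsmRecord]:
    """Read a TSV PSM table into records, validating against the plex design.

    Parameters
    ----------
    path : file path of a tab-separated PSM table with a header row.
    design : the plex the table belongs to; its channel count fixes the
        number of expected ``reporter_*`` columns.
    colmap : optional mapping from the file's column names to the canonical
        schema names, for alternative PSM-table dialects.

    Raises
    ------
    SchemaError : a required column is absent (the error names it).
    DesignError : reporter column count disagrees with the design, or the
        table's plex identifiers do not match ``design.plex_id``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if colmap:
        df = df.rename(columns=colmap)

    for col in PSM_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"PSM table {path} is missing required column '{col}'")

    rep_cols = [c for c in df.columns if c.startswith("reporter_")]
    rep_cols.sort(key=lambda c: int(c.split("_")[1]))
    if len(rep_cols) != design.n_channels:
        raise DesignError(
            f"PSM table has {len(rep_cols)} reporter columns but design "
            f"{design.plex_id} declares {design.n_channels} channels"
        )

    known = set(PSM_COLUMNS) | set(rep_cols)
    extra_cols = [c for c in df.columns if c not in known]

    records: list[PsmRecord] = []
    for row in df.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        if d["plex"] != design.plex_id:
            raise DesignError(
                f"PSM row has plex '{d['plex']}' but design is '{design.plex_id}'"
            )
        reporter: list[float | None] = []
        for c in rep_cols:
            cell = d[c].strip()
            reporter.append(float(cell) if cell != "" else None)
        records.append(
            PsmRecord(
                plex_id=d["plex"],
                run_id=d["run"],
                spectrum_id=d["spectrum"],
                peptide=d["peptide"],
                charge=int(d["charge"]),
                entry_id=d["entry"],
                assignment=d["assignment"],
                is_contaminant=d["contaminant"] in ("1", "True", "true"),
                has_tmt_label=d["tmt_labeled"] in ("1", "True", "true"),
                ms1_intensity=float(d["ms1_intensity"]),
                reporter=reporter,
                purity=float(d["purity"]),
                psm_probability=float(d["probability"]),
                extra={c: d[c] for c in extra_cols},
            )
        )
    return records


def write_psm_table(psms: Sequence[PsmRecord], path: str | Path) -> None:
    """Write records to the canonical TSV schema (missing reporters -> empty cells)."""
    path = Path(path)
    n_rep = len(psms[0].reporter) if psms else 10
    header = PSM_COLUMNS + _reporter_columns(n_rep)
    extra_cols = sorted({k for p in psms for k in p.extra})
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header + extra_cols)
        for p in psms:
            row = [
                p.plex_id,
                p.run_id,
                p.spectrum_id,
                p.peptide,
                p.charge,
                p.entry_id,
                p.assignment,
                int(p.is_contaminant),
                int(p.has_tmt_label),
                repr(p.ms1_intensity),
                repr(p.purity),
                repr(p.psm_probability),
            ]
            row += [
                "" if (v is None or (isinstance(v, float) and math.isnan(v))) else repr(float(v))
                for v in p.reporter
            ]
            row += [p.extra.get(c, "") for c in extra_cols]
            w.writerow(row)


def read_design(path: str | Path) -> list[PlexDesign]:
    """Read a design TSV (columns: plex, channel, sample, role, phenotype)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("plex", "channel", "sample", "role", "phenotype"):
        if col not in df.columns:
            raise SchemaError(f"design table is missing required column '{col}'")
    designs = []
    for plex_id, grp in df.groupby("plex", sort=False):
        channels = [
            PlexChannel(
                channel_label=r.channel,
                sample_id=r.sample,
                role=r.role,
                phenotype=r.phenotype or "n/a",
            )
            for r in grp.itertuples(index=False)
        ]
        designs.append(PlexDesign(plex_id=str(plex_id), channels=channels))
    return designs


def write_design(designs: Sequence[PlexDesign], path: str | Path) -> None:
    rows = []
    for d in designs:
        for c in d.channels:
            rows.append(
                {
                    "plex": d.plex_id,
                    "channel": c.channel_label,
                    "sample": c.sample_id,
                    "role": c.role,
                    "phenotype": c.phenotype,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def validate_design(designs: Sequence[PlexDesign]) -> list[str]:
    """Validate a multi-plex design set; return the non-reference sample columns.

    Confirms one reference channel per plex (enforced per plex on
    construction) and that individual sample_ids are not duplicated across
    plexes; pool aliquots (roles ``bridge_pool``/``validation_pool``) may
    recur across plexes by design. The returned identifiers — one per
    non-reference channel, globally unique — are the columns of all
    downstream matrices. Order-insensitive over plexes up to column order,
    and idempotent.
    """
    if len(designs) < 1:
        raise DesignError("need at least one plex")
    seen: dict[str, str] = {}
    out: list[str] = []
    for d in sorted(designs, key=lambda d: d.plex_id):
        for c in d.sample_channels():
            if c.role == "individual":
                if c.sample_id in seen:
                    raise DesignError(
                        f"sample '{c.sample_id}' appears in plexes "
                        f"{seen[c.sample_id]} and {d.plex_id}"
                    )
                seen[c.sample_id] = d.plex_id
            out.append(d.global_sample_id(c))
    return out


def write_matrix(m: QuantMatrix, path: str | Path) -> None:
    """Write a quant matrix as TSV: entries as rows, samples as columns.

    Missing cells are encoded as empty strings; finite values round-trip
    bit-identically (written via ``repr``).
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow([f"entry[{m.level}|{m.kind}]"] + list(m.values.columns))
        for entry, row in m.values.iterrows():
            w.writerow(
                [entry]
                + ["" if pd.isna(v) else repr(float(v)) for v in row.to_numpy()]
            )


def read_matrix(path: str | Path) -> QuantMatrix:
    """Read back a matrix written by :func:`write_matrix`."""
    path = Path(path)
    with open(path) as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r)
        tag = header[0]
        level, kind = "gene", "ratio"
        if tag.startswith("entry[") and tag.endswith("]"):
            level, kind = tag[len("entry[") : -1].split("|")
        cols = header[1:]
        entries, data = [], []
        for row in r:
            entries.append(row[0])
            data.append([float(v) if v != "" else np.nan for v in row[1:]])
    values = pd.DataFrame(data, index=entries, columns=cols, dtype=float)
    if not entries:
        values = pd.DataFrame(
            np.empty((0, len(cols))), index=pd.Index([]), columns=cols, dtype=float
        )
    return QuantMatrix(values, level=level, kind=kind)


def read_clinical(path: str | Path) -> list[ClinicalAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "phenotype", "hemoglobin"):
        if col not in df.columns:
            raise SchemaError(f"clinical table is missing required column '{col}'")
    out = []
    for r in df.itertuples(index=False):
        hb = float(r.hemoglobin) if r.hemoglobin != "" else float("nan")
        bili = (
            float(r.bilirubin)
            if "bilirubin" in df.columns and r.bilirubin != ""
            else float("nan")
        )
        out.append(
            ClinicalAnnotation(
                sample_id=r.sample_id, phenotype=r.phenotype, hemoglobin=hb, bilirubin=bili
            )
        )
    return out


def write_clinical(annotations: Iterable[ClinicalAnnotation], path: str | Path) -> None:
    rows = []
    for a in annotations:
        rows.append(
            {
                "sample_id": a.sample_id,
                "phenotype": a.phenotype,
                "hemoglobin": "" if math.isnan(a.hemoglobin) else repr(a.hemoglobin),
                "bilirubin": "" if math.isnan(a.bilirubin) else repr(a.bilirubin),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_manifest(path: str | Path, command: str, params: dict) -> None:
    """Log parameter provenance for a CLI run as JSON."""
    payload = {"command": command, "params": params}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
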