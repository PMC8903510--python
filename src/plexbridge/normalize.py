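"""Bridge-channel normalization of multi-plex TMT data.

Each plex carries one pooled reference (bridge) channel. Per PSM, reporter
intensities are log2-transformed and the reference channel is subtracted,
converting every sample channel to a log2 ratio to the common reference
scale — per-plex multiplicative batch effects applied to all channels of a
plex cancel exactly in this ratio space. Ratios are grouped per entry
(gene/protein/peptide) and sample, Tukey-fenced (values outside
[Q1 - 1.5*IQR, Q3 + 1.5*IQR] dropped) and summarized by the median. The
resulting entries-by-samples ratio table R_ij is then MAD-normalized per
sample::

    M_i    = median_j(R_ij)           (per-sample median)
    RC_ij  = R_ij - M_i               (centered)
    MAD_i  = median_j(|RC_ij|)        (per-sample scale, no consistency constant)
    M_0    = median_i(M_i),  MAD_0 = median_i(MAD_i)   (global, across all plexes)
    RN_ij  = (RC_ij / MAD_i) * MAD_0 + M_0

so every sample's median and MAD land exactly on the global values. Finally
the ratios are put back on an absolute log2 intensity scale using a per-entry
reference intensity: in each plex the weighted sum of the MS1 intensities of
the (up to) 3 most MS1-intense peptide ions, weighted by each PSM's reference
share of total reporter intensity; plexes where the entry was never
quantified are imputed with the global minimum reference intensity before
averaging across all plexes::

    A_ij = RN_ij + log2(REF_i),  REF_i = mean_k(REF_ik)

Quantile conventions (quartiles and the filter percentile) use linear
interpolation between order statistics; :func:`quantile` centralizes this so
one switch changes the convention everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .filters import FilterReport, apply_quality_filters, collapse_redundant
from .types import PlexDesign, PsmRecord, QuantMatrix

__all__ = [
    "NormalizationParams",
    "quantile",
    "compute_ratios",
    "iqr_trim",
    "summarize_entry",
    "mad_normalize",
    "reference_intensity",
    "assemble_abundance",
    "normalize_plexes",
]


def quantile(values: np.ndarray, q: float | Sequence[float]):
    """Sample quantile by linear interpolation between order statistics."""
    return np.quantile(np.asarray(values, dtype=float), q, method="linear")


@dataclass
class NormalizationParams:
    """Fitted normalization quantities, kept for provenance and diagnostics."""

    m_i: pd.Series  # per-sample median ratio
    mad_i: pd.Series  # per-sample median absolute deviation
    m0: float
    mad0: float
    ref_ik: pd.DataFrame | None = None  # entries x plexes reference intensities
    ref_i: pd.Series | None = None  # per-entry mean reference intensity
    global_min_ref: float = float("nan")
    flagged_zero_mad: list[str] = field(default_factory=list)
    n_ref_zero_skipped: int = 0
    n_entries_dropped_nonpositive_ref: int = 0

    def to_dict(self) -> dict:
        d = {
            "M0": self.m0,
            "MAD0": self.mad0,
            "M_i": self.m_i.to_dict(),
            "MAD_i": self.mad_i.to_dict(),
            "global_min_ref": self.global_min_ref,
            "flagged_zero_mad": self.flagged_zero_mad,
            "n_ref_zero_skipped": self.n_ref_zero_skipped,
        }
        if self.ref_i is not None:
            d["REF_i"] = self.ref_i.to_dict()
        return d


def compute_ratios(psms: Sequence[PsmRecord], design: PlexDesign) -> pd.DataFrame:
    """PSM-level log2 ratios to the reference channel.

    One row per (PSM, non-reference channel) with a nonmissing, nonzero
    channel intensity: ``ratio = log2(I_channel) - log2(I_reference)``.
    Zero channel intensity means non-detection and yields no observation
    (never -inf). PSMs whose reference intensity is zero are skipped
    entirely (log2 undefined); their count is in ``df.attrs['n_ref_zero']``.
    """
    ref_idx = design.reference_index
    sample_channels = [
        (i, design.global_sample_id(c))
        for i, c in enumerate(design.channels)
        if c.role != "reference"
    ]
    rows = []
    n_ref_zero = 0
    for p in psms:
        ref = p.reporter[ref_idx]
        if ref is None or (isinstance(ref, float) and np.isnan(ref)):
            continue  # guaranteed filtered upstream (rule b)
        if ref == 0:
            n_ref_zero += 1
            continue
        lref = np.log2(ref)
        for idx, sample_id in sample_channels:
            v = p.reporter[idx]
            if v is None or (isinstance(v, float) and np.isnan(v)) or v == 0:
                continue
            rows.append(
                (p.entry_id, sample_id, design.plex_id, np.log2(v) - lref)
            )
    df = pd.DataFrame(rows, columns=["entry_id", "sample_id", "plex_id", "ratio"])
    df.attrs["n_ref_zero"] = n_ref_zero
    return df


def iqr_trim(values: Sequence[float]) -> np.ndarray:
    """Drop Tukey-fence outliers: keep Q1 - 1.5*IQR <= v <= Q3 + 1.5*IQR.

    Quartiles use the linear-interpolation convention. Bounds are inclusive;
    a single value is always kept. Empty input is a domain error.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("iqr_trim requires at least one value")
    q1, q3 = quantile(v, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return v[(v >= lo) & (v <= hi)]


def summarize_entry(
    observations: pd.DataFrame,
    sample_ids: Sequence[str],
    level: str = "gene",
) -> QuantMatrix:
    """Median of IQR-trimmed PSM ratios per (entry, sample) -> unified ratio matrix.

    ``observations`` is the concatenation of :func:`compute_ratios` outputs
    over all plexes; ``sample_ids`` fixes the column set (so samples with no
    observations still appear, entirely missing). Cells with no observations
    stay missing — a protein absent from one plex yields wholly missing
    columns for that plex's samples (inter-plex dropout).
    """
    cells = (
        observations.groupby(["entry_id", "sample_id"], sort=False)["ratio"]
        .apply(lambda v: float(np.median(iqr_trim(v.to_numpy()))))
        .unstack("sample_id")
    )
    entries = sorted(observations["entry_id"].unique())
    cells = cells.reindex(index=entries, columns=list(sample_ids))
    return QuantMatrix(cells, level=level, kind="ratio")


def mad_normalize(
    matrix: QuantMatrix,
) -> tuple[QuantMatrix, NormalizationParams]:
    """MAD-normalize each sample column onto the global median/MAD scale.

    Missing cells stay missing. A sample with MAD_i = 0 (degenerate spread)
    is flagged and gets scale factor 1 instead of an undefined division.
    """
    r = matrix.values
    m_i = r.median(axis=0, skipna=True)
    centered = r.sub(m_i, axis=1)
    mad_i = centered.abs().median(axis=0, skipna=True)
    m0 = float(m_i.median())
    mad0 = float(mad_i.median())

    flagged = [str(s) for s in mad_i.index[mad_i == 0]]
    scale = mad_i.replace(0.0, np.nan)
    factors = (mad0 / scale).fillna(1.0)
    rn = centered.mul(factors, axis=1) + m0

    params = NormalizationParams(
        m_i=m_i, mad_i=mad_i, m0=m0, mad0=mad0, flagged_zero_mad=flagged
    )
    return QuantMatrix(rn, level=matrix.level, kind="normalized_ratio"), params


def reference_intensity(
    psms_by_plex: dict[str, Sequence[PsmRecord]],
    designs: Sequence[PlexDesign],
    entries: Sequence[str] | None = None,
    impute_global_min: bool = True,
) -> tuple[pd.DataFrame, pd.Series, float]:
    """Estimate per-entry reference intensities REF_ik and their mean REF_i.

    For each entry and plex, the (up to) 3 PSMs with the largest MS1
    precursor intensity (after redundant-PSM collapse) contribute
    ``ms1 * reference_share``, where ``reference_share`` is the reference
    channel's fraction of the PSM's total reporter intensity. Plexes where
    the entry has no quantified PSM are imputed with the global minimum
    observed REF value before averaging over all plexes; with
    ``impute_global_min=False`` the mean runs over observed plexes only.

    Returns (REF_ik table with NaN for unobserved cells, REF_i series,
    global minimum used for imputation).
    """
    plex_ids = [d.plex_id for d in designs]
    ref_idx = {d.plex_id: d.reference_index for d in designs}

    per_cell: dict[tuple[str, str], float] = {}
    for plex_id in plex_ids:
        by_entry: dict[str, list[PsmRecord]] = {}
        for p in psms_by_plex.get(plex_id, []):
            by_entry.setdefault(p.entry_id, []).append(p)
        for entry_id, group in by_entry.items():
            top = sorted(group, key=lambda p: -p.ms1_intensity)[:3]
            total = 0.0
            for p in top:
                summed = p.summed_reporter()
                if summed <= 0:
                    continue
                ref_val = p.reporter[ref_idx[plex_id]]
                if ref_val is None or (isinstance(ref_val, float) and np.isnan(ref_val)):
                    continue
                total += p.ms1_intensity * (float(ref_val) / summed)
            per_cell[(entry_id, plex_id)] = total

    if entries is None:
        entries = sorted({e for (e, _) in per_cell})
    ref_ik = pd.DataFrame(np.nan, index=list(entries), columns=plex_ids, dtype=float)
    for (e, k), v in per_cell.items():
        if e in ref_ik.index:
            ref_ik.loc[e, k] = v

    observed = ref_ik.to_numpy()
    observed = observed[~np.isnan(observed)]
    global_min = float(observed.min()) if observed.size else float("nan")

    if impute_global_min:
        ref_i = ref_ik.fillna(global_min).mean(axis=1)
    else:
        ref_i = ref_ik.mean(axis=1, skipna=True)
    return ref_ik, ref_i, global_min


def assemble_abundance(
    rn: QuantMatrix, ref_i: pd.Series
) -> tuple[QuantMatrix, int]:
    """A_ij = RN_ij + log2(REF_i); entries with REF_i <= 0 are excluded.

    Returns the unified abundance matrix (all plexes' samples as columns)
    and the count of entries dropped for nonpositive reference intensity.
    """
    ref = ref_i.reindex(rn.values.index)
    bad = ref.isna() | (ref <= 0)
    n_dropped = int(bad.sum())
    keep = rn.values.loc[~bad.to_numpy()]
    a = keep.add(np.log2(ref[~bad]), axis=0)
    return QuantMatrix(a, level=rn.level, kind="abundance"), n_dropped


def normalize_plexes(
    psm_tables: dict[str, Sequence[PsmRecord]],
    designs: Sequence[PlexDesign],
    level: str = "gene",
    intensity_percentile: float | None = 0.05,
    min_probability: float | None = None,
    impute_global_min: bool = True,
) -> tuple[QuantMatrix, QuantMatrix, NormalizationParams, dict[str, FilterReport]]:
    """Full chain: quality filter -> collapse -> ratios -> summarize -> MAD -> abundance.

    Returns (abundance matrix, normalized ratio matrix, params, filter reports).
    """
    designs = list(designs)
    by_id = {d.plex_id: d for d in designs}
    if set(psm_tables) - set(by_id):
        raise ValueError(f"PSM tables for unknown plexes: {set(psm_tables) - set(by_id)}")

    reports: dict[str, FilterReport] = {}
    kept_by_plex: dict[str, list[PsmRecord]] = {}
    obs_frames = []
    n_ref_zero = 0
    for d in designs:
        kept, rep = apply_quality_filters(
            psm_tables.get(d.plex_id, []),
            d,
            intensity_percentile=intensity_percentile,
            min_probability=min_probability,
        )
        kept = collapse_redundant(kept)
        reports[d.plex_id] = rep
        kept_by_plex[d.plex_id] = kept
        obs = compute_ratios(kept, d)
        n_ref_zero += obs.attrs.get("n_ref_zero", 0)
        obs_frames.append(obs)

    observations = pd.concat(obs_frames, ignore_index=True)
    sample_ids = [d.global_sample_id(c) for d in designs for c in d.sample_channels()]
    ratios = summarize_entry(observations, sample_ids, level=level)
    rn, params = mad_normalize(ratios)
    ref_ik, ref_i, global_min = reference_intensity(
        kept_by_plex, designs, entries=ratios.entry_ids, impute_global_min=impute_global_min
    )
    abundance, n_dropped = assemble_abundance(rn, ref_i)
    params.ref_ik = ref_ik
    params.ref_i = ref_i
    params.global_min_ref = global_min
    params.n_ref_zero_skipped = n_ref_zero
    params.n_entries_dropped_nonpositive_ref = n_dropped
    return abundance, rn, params, reports
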