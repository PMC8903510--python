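"""PSM quality filtering and redundant-PSM collapse.

Four quality rules are applied per plex, in order:

(a) no TMT label;
(b) missing quantification in the reference channel;
(c) precursor-ion purity below 50% (strict: purity 0.50 is kept);
(d) summed reporter-ion intensity (across all channels) at or below the
    5th percentile of the summed intensities of the PSMs surviving (a)-(c).

PSMs flagged as mapping to external contaminant proteins are also removed
(counted separately, before the percentile is computed, since contaminants
should not shape the intensity threshold). Both unique and razor peptide
assignments are retained. The 5th percentile uses the linear-interpolation
sample quantile and the boundary is inclusive: values <= the percentile
value are removed — except values tied with the plex maximum, which can
never be low-intensity (this keeps the degenerate all-equal case intact).

Redundant PSMs — several spectra in the same MS run matching the same
peptide ion (sequence incl. modifications + charge) — are collapsed to the
single PSM with the highest summed reporter intensity; ties break on
lexicographically smallest spectrum_id so the result is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .types import PlexDesign, PsmRecord

__all__ = ["FilterReport", "apply_quality_filters", "collapse_redundant"]

RULES = ("no_label", "missing_reference", "low_purity", "contaminant", "low_intensity")


@dataclass
class FilterReport:
    """Accounting of removals per rule; kept + removed reconciles to the input."""

    plex_id: str
    counts_removed: dict[str, int] = field(default_factory=dict)
    counts_kept: int = 0
    n_input: int = 0
    intensity_threshold: float = float("nan")
    min_probability: float | None = None

    @property
    def total_removed(self) -> int:
        return sum(self.counts_removed.values())

    def reconciles(self) -> bool:
        return self.counts_kept + self.total_removed == self.n_input


def _is_missing(v: float | None) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


def apply_quality_filters(
    psms: Sequence[PsmRecord],
    design: PlexDesign,
    intensity_percentile: float | None = 0.05,
    intensity_threshold: float | None = None,
    min_probability: float | None = None,
) -> tuple[list[PsmRecord], FilterReport]:
    """Apply quality rules (a)-(d) plus contaminant removal to one plex's PSMs.

    Parameters
    ----------
    psms : PSMs, all belonging to ``design``'s plex.
    intensity_percentile : quantile level for rule (d), computed over
        survivors of the preceding rules; ``None`` disables the rule.
    intensity_threshold : if given, rule (d) uses this frozen absolute
        threshold instead of recomputing the percentile — re-application
        with the threshold recorded in a previous :class:`FilterReport` is
        then idempotent.
    min_probability : optional re-application of the upstream PSM
        probability cut (a passthrough; normally already applied upstream).

    Returns the kept PSMs (input order preserved) and a report whose
    per-rule counts reconcile exactly with input/output sizes. Empty input
    yields empty output with a zeroed report.
    """
    report = FilterReport(
        plex_id=design.plex_id,
        counts_removed={r: 0 for r in RULES},
        n_input=len(psms),
        min_probability=min_probability,
    )
    if min_probability is not None:
        report.counts_removed["low_probability"] = 0
    ref_idx = design.reference_index

    survivors: list[PsmRecord] = []
    for p in psms:
        if p.plex_id != design.plex_id:
            raise ValueError(
                f"PSM from plex '{p.plex_id}' passed with design '{design.plex_id}'"
            )
        if min_probability is not None and p.psm_probability < min_probability:
            report.counts_removed["low_probability"] += 1
        elif not p.has_tmt_label:
            report.counts_removed["no_label"] += 1
        elif _is_missing(p.reporter[ref_idx]):
            report.counts_removed["missing_reference"] += 1
        elif p.purity < 0.5:
            report.counts_removed["low_purity"] += 1
        elif p.is_contaminant:
            report.counts_removed["contaminant"] += 1
        else:
            survivors.append(p)

    if survivors and intensity_percentile is None and intensity_threshold is None:
        kept = survivors
    elif survivors:
        sums = np.array([p.summed_reporter() for p in survivors])
        if intensity_threshold is None:
            intensity_threshold = float(np.quantile(sums, intensity_percentile))
        # Inclusive boundary, but a PSM tied with the plex maximum cannot be
        # "in the 5th percentile": guards the degenerate all-equal case.
        max_sum = float(sums.max())
        kept = []
        for p in survivors:
            s = p.summed_reporter()
            if s <= intensity_threshold and s < max_sum:
                report.counts_removed["low_intensity"] += 1
            else:
                kept.append(p)
        report.intensity_threshold = float(intensity_threshold)
    else:
        kept = []

    report.counts_kept = len(kept)
    assert report.reconciles()
    return kept, report


def collapse_redundant(psms: Sequence[PsmRecord]) -> list[PsmRecord]:
    """Keep one PSM per peptide ion per MS run: the highest summed TMT intensity.

    Grouping key is (plex, run, peptide sequence incl. modifications, charge).
    Ties on summed intensity break on lexicographically smallest spectrum_id.
    Output preserves first-appearance order of the groups.
    """
    best: dict[tuple, PsmRecord] = {}
    order: list[tuple] = []
    for p in psms:
        key = p.peptide_ion()
        cur = best.get(key)
        if cur is None:
            best[key] = p
            order.append(key)
        else:
            s_new, s_cur = p.summed_reporter(), cur.summed_reporter()
            if s_new > s_cur or (s_new == s_cur and p.spectrum_id < cur.spectrum_id):
                best[key] = p
    return [best[k] for k in order]
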