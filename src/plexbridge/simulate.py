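"""Multi-plex TMT experiment simulator with known ground truth.

Emulates the study design every downstream stage is built for: several TMT
10-plexes, each carrying individual control (CTL) and disease (PDR) vitreous
samples, one aliquot of a pooled validation sample (pool 1, controls only)
and one aliquot of the pooled bridge/reference sample (pool 2, a mixture of
all individual samples). Pool channels are exact per-plex linear mixtures of
the simulated individual-sample true abundances (before noise), so they act
as genuine technical replicates and bridge channels.

Generative model (log2 scale throughout):

* protein baseline  beta_i ~ N(baseline_log2_mean, baseline_log2_sd)
  (log-normal intensity);
* disease effect    delta_i = 0 with probability pi0, otherwise
  g_i * protein_sd with g_i ~ N(0, effect_size_sd) — so the population
  standardized difference (Hedges'-g scale) of a non-null protein is g_i;
* biological noise  e_is ~ N(0, protein_sd) per individual sample;
* per-plex batch    d_ik ~ N(0, plex_shift_sd) added to ALL channels of
  plex k (including the reference) — invisible in ratio space by design;
* PSM sampling depth o ~ N(0, ms1_log2_sd) shared by a PSM's MS1 precursor
  intensity and its reporters;
* reporter noise    eps ~ N(0, tech_sd) per channel per PSM.

Reporter intensity of channel c in a PSM of protein i is then
``2 ** (truth(channel) + d_ik + o + eps)``.

Dropout is injected after quantification: a protein may be wholly removed
from a subset of plexes (inter-plex dropout) or blanked for a strict subset
of one plex's channels (intra-plex dropout). Because the downstream quality
filters (notably the bottom-5% summed-intensity rule) can themselves erase
a low-abundance protein from a plex, the ground-truth ``dropout_class`` is
the REALIZED class: after emitting the PSM tables the generator applies the
filter chain and classifies the surviving presence pattern with its own
straight-line classifier; the injected class is kept separately.

Seeding: a master seed feeds explicit per-plex substreams
(``SeedSequence(seed, spawn_key=(1, k))``) for all plex-local noise, and a
dedicated global substream for protein-level truth — baselines, effects, and
annotations depend only on ``n_proteins`` and the seed, not on the plex
count. (Injected-dropout plex targeting draws subset sizes relative to
``n_plexes`` and therefore re-randomizes when plexes are added.) All normal
draws are standard normals scaled afterwards, so setting a variance to zero
never changes stream consumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filters import apply_quality_filters, collapse_redundant
from .qc import DEFAULT_PLASMA_GENES, DEFAULT_RBC_GENES, HB_BANDS
from .types import ClinicalAnnotation, PlexChannel, PlexDesign, PsmRecord

__all__ = ["SimConfig", "GroundTruth", "SimResult", "simulate_experiment", "truth_summary"]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


class ConfigError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


@dataclass
class SimConfig:
    """Study-design and noise parameters of the simulated experiment.

    Defaults mirror the validated vitreous study design: four 10-plexes, 10
    control and 22 PDR individuals, a bridge pool and a validation pool per
    plex, pi0 = 0.7 null proteins, and dropout rates matching the observed
    complete/inter-plex/intra-plex partition. Noise magnitudes (reporter
    noise, biological SD) are tunables; the defaults place technical-
    replicate correlations in the high-0.9s band typical of TMT data.
    """

    n_plexes: int = 4
    channels_per_plex: int = 10
    n_ctl: int = 10
    n_pdr: int = 22
    n_proteins: int = 1200
    peptides_per_protein: float = 3.0  # mean of 1 + Poisson(mean - 1)
    psms_per_peptide: float = 2.0  # mean of 1 + Poisson(mean - 1)
    n_fractions: int = 2  # MS runs (fractions) per plex
    pi0: float = 0.7
    effect_size_sd: float = 1.5  # SD of non-null Hedges'-g-scale effects
    protein_sd: float = 0.5  # between-sample biological SD, log2
    tech_sd: float = 0.15  # PSM-level reporter noise SD, log2
    plex_shift_sd: float = 0.5  # per-plex per-protein batch shift SD, log2
    baseline_log2_mean: float = 16.0
    baseline_log2_sd: float = 2.0
    ms1_log2_sd: float = 1.0
    purity_alpha: float = 8.0  # Beta parameters for precursor purity
    purity_beta: float = 2.0
    frac_unlabeled: float = 0.01
    frac_razor: float = 0.2
    frac_contaminant: float = 0.005  # PSMs remapped to external contaminants
    interplex_dropout_rate: float = 0.34
    intraplex_dropout_rate: float = 0.035
    n_plasma: int = 23
    n_rbc: int = 7
    rbc_pdr_upshift: float = 2.0  # additive log2 upshift of erythroid proteins in PDR
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pi0", "frac_unlabeled", "frac_razor", "frac_contaminant",
                     "interplex_dropout_rate", "intraplex_dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.pi0 <= 0:
            raise ConfigError("pi0 must be in (0,1]")
        for name in ("n_plexes", "channels_per_plex", "n_ctl", "n_pdr", "n_proteins"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        budget = self.n_plexes * (self.channels_per_plex - 2)
        if self.n_ctl + self.n_pdr > budget:
            raise ConfigError(
                f"{self.n_ctl} CTL + {self.n_pdr} PDR samples exceed the channel "
                f"budget of {budget} (={self.n_plexes} plexes x "
                f"{self.channels_per_plex - 2} individual channels)"
            )
        if self.interplex_dropout_rate + self.intraplex_dropout_rate > 1:
            raise ConfigError("dropout rates sum above 1")


@dataclass
class GroundTruth:
    """Per-protein truth ledger, joinable to downstream outputs by entry_id.

    ``frame`` columns: true_log2fc (PDR - CTL), is_null, true_g,
    injected_dropout (what the generator removed), dropout_class (the
    realized missingness class after quality filtering), annotation
    (plasma/rbc/other). ``plex_shifts`` holds d_ik; ``sample_truth`` the
    noise-free per-sample log2 abundances t_is (before plex shifts).
    """

    frame: pd.DataFrame
    plex_shifts: pd.DataFrame
    sample_truth: pd.DataFrame
    pool1_log2: pd.Series = field(default_factory=pd.Series)
    pool2_log2: pd.Series = field(default_factory=pd.Series)


@dataclass
class SimResult:
    psm_tables: dict[str, list[PsmRecord]]
    designs: list[PlexDesign]
    clinical: list[ClinicalAnnotation]
    truth: GroundTruth


def _classify_realized(per_plex: dict[str, tuple[int, int]]) -> str:
    """Straight-line presence classifier (independent of the QC module)."""
    vals = list(per_plex.values())
    if all(m == 0 for m, _ in vals):
        return "absent"
    for m, n in vals:
        if 0 < m < n:
            return "intraplex"
    for m, _n in vals:
        if m == 0:
            return "interplex"
    return "complete"


def _build_designs(cfg: SimConfig) -> tuple[list[PlexDesign], list[str], list[str]]:
    """Allocate individuals round-robin across plexes; pools in the last channels."""
    per_plex: list[list[tuple[str, str, str]]] = [[] for _ in range(cfg.n_plexes)]
    ctl_ids = [f"CTL{i + 1:03d}" for i in range(cfg.n_ctl)]
    pdr_ids = [f"PDR{i + 1:03d}" for i in range(cfg.n_pdr)]
    for i, sid in enumerate(ctl_ids):
        per_plex[i % cfg.n_plexes].append((sid, "individual", "CTL"))
    # fill PDR into the plexes with remaining room, round-robin
    k = 0
    cap = cfg.channels_per_plex - 2
    for sid in pdr_ids:
        while len(per_plex[k % cfg.n_plexes]) >= cap:
            k += 1
        per_plex[k % cfg.n_plexes].append((sid, "individual", "PDR"))
        k += 1
    designs = []
    for p in range(cfg.n_plexes):
        plex_id = f"plex{p + 1}"
        channels = [
            PlexChannel(channel_label=f"ch{j + 1:02d}", sample_id=sid, role=role, phenotype=ph)
            for j, (sid, role, ph) in enumerate(per_plex[p])
        ]
        nxt = len(channels)
        channels.append(
            PlexChannel(f"ch{nxt + 1:02d}", f"pool1.{p + 1}", "validation_pool", "n/a")
        )
        channels.append(
            PlexChannel(f"ch{nxt + 2:02d}", f"pool2.{p + 1}", "reference", "n/a")
        )
        designs.append(PlexDesign(plex_id=plex_id, channels=channels))
    return designs, ctl_ids, pdr_ids


def _simulate_clinical(
    cfg: SimConfig, ctl_ids: list[str], pdr_ids: list[str], rng: np.random.Generator
) -> list[ClinicalAnnotation]:
    """Hemoglobin by subphenotype band: cycle L/M/H so all bands are populated,
    then draw uniformly within the printed concentration band."""
    out = [ClinicalAnnotation(s, "CTL") for s in ctl_ids]
    bands = list(HB_BANDS.values())
    for i, s in enumerate(pdr_ids):
        lo, hi = bands[i % 3]
        hb = lo + (hi - lo) * rng.uniform()
        bili = rng.uniform(0.002, 0.01)
        out.append(ClinicalAnnotation(s, "PDR", hemoglobin=hb, bilirubin=bili))
    return out


def simulate_experiment(cfg: SimConfig) -> SimResult:
    """Generate PSM tables, designs, clinical annotations, and ground truth.

    Deterministic for a fixed ``cfg.seed``; the same seed reproduces
    byte-identical PSM tables.
    """
    designs, ctl_ids, pdr_ids = _build_designs(cfg)
    sample_ids = ctl_ids + pdr_ids
    n_s = len(sample_ids)
    is_pdr = np.array([s.startswith("PDR") for s in sample_ids])

    g_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))

    entries = [f"G{i + 1:04d}" for i in range(cfg.n_proteins)]
    # annotation: first n_rbc -> rbc, next n_plasma -> plasma, permuted
    annot = np.array(["other"] * cfg.n_proteins, dtype=object)
    perm = g_rng.permutation(cfg.n_proteins)
    annot[perm[: cfg.n_rbc]] = "rbc"
    annot[perm[cfg.n_rbc : cfg.n_rbc + cfg.n_plasma]] = "plasma"
    # give annotated proteins recognizable gene symbols (while ids stay unique)
    for j, idx in enumerate(perm[: cfg.n_rbc]):
        if j < len(DEFAULT_RBC_GENES):
            entries[idx] = DEFAULT_RBC_GENES[j]
    for j, idx in enumerate(perm[cfg.n_rbc : cfg.n_rbc + cfg.n_plasma]):
        if j < len(DEFAULT_PLASMA_GENES):
            entries[idx] = DEFAULT_PLASMA_GENES[j]

    beta = cfg.baseline_log2_mean + cfg.baseline_log2_sd * g_rng.standard_normal(
        cfg.n_proteins
    )
    nonnull = g_rng.uniform(size=cfg.n_proteins) >= cfg.pi0
    true_g = np.where(nonnull, cfg.effect_size_sd * g_rng.standard_normal(cfg.n_proteins), 0.0)
    true_fc = true_g * cfg.protein_sd
    # blood-protein conventions: plasma proteins carry no phenotype effect;
    # erythroid proteins are upshifted in PDR (hemorrhage contamination).
    true_fc[annot == "plasma"] = 0.0
    true_fc[annot == "rbc"] += cfg.rbc_pdr_upshift
    true_g = np.where(cfg.protein_sd > 0, true_fc / max(cfg.protein_sd, 1e-300), 0.0)
    is_null = true_fc == 0.0

    # injected dropout assignment + per-protein target plex/channel subsets
    u = g_rng.uniform(size=cfg.n_proteins)
    injected = np.where(
        u < cfg.intraplex_dropout_rate,
        "intraplex",
        np.where(u < cfg.intraplex_dropout_rate + cfg.interplex_dropout_rate, "interplex", "none"),
    )
    drop_plexes: list[set[int]] = []
    intra_target: list[tuple[int, set[int]] | None] = []
    for i in range(cfg.n_proteins):
        if injected[i] == "interplex" and cfg.n_plexes > 1:
            size = int(g_rng.integers(1, cfg.n_plexes))
            drop_plexes.append(set(g_rng.choice(cfg.n_plexes, size=size, replace=False).tolist()))
            intra_target.append(None)
        elif injected[i] == "intraplex":
            plex = int(g_rng.integers(0, cfg.n_plexes))
            n_nonref = cfg.channels_per_plex - 1
            size = int(g_rng.integers(1, max(2, n_nonref)))
            chans = set(g_rng.choice(n_nonref, size=size, replace=False).tolist())
            drop_plexes.append(set())
            intra_target.append((plex, chans))
        else:
            drop_plexes.append(set())
            intra_target.append(None)

    # peptide inventory (global: same peptide ions exist in every plex)
    n_pep = 1 + g_rng.poisson(max(cfg.peptides_per_protein - 1.0, 0.0), size=cfg.n_proteins)
    peptides: list[list[tuple[str, int, int]]] = []  # (sequence, charge, fraction)
    for i in range(cfg.n_proteins):
        plist = []
        for _ in range(n_pep[i]):
            length = int(g_rng.integers(8, 16))
            seq = "".join(g_rng.choice(_AA, size=length))
            charge = int(g_rng.integers(2, 4))
            fraction = int(g_rng.integers(0, cfg.n_fractions))
            plist.append((seq, charge, fraction))
        peptides.append(plist)

    # per-sample biological truth
    e = cfg.protein_sd * g_rng.standard_normal((cfg.n_proteins, n_s))
    t = beta[:, None] + np.where(is_pdr[None, :], true_fc[:, None], 0.0) + e
    lin = 2.0**t
    pool1 = np.log2(lin[:, ~is_pdr].mean(axis=1))  # controls-only validation pool
    pool2 = np.log2(lin.mean(axis=1))  # bridge pool: all individuals

    clinical = _simulate_clinical(cfg, ctl_ids, pdr_ids, g_rng)

    sample_col = {s: j for j, s in enumerate(sample_ids)}
    psm_tables: dict[str, list[PsmRecord]] = {}
    shifts = np.zeros((cfg.n_proteins, cfg.n_plexes))

    for p, design in enumerate(designs):
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1, p)))
        d_k = cfg.plex_shift_sd * rng.standard_normal(cfg.n_proteins)
        shifts[:, p] = d_k
        # noise-free channel truth for this plex
        chan_truth = np.empty((cfg.n_proteins, design.n_channels))
        for ci, ch in enumerate(design.channels):
            if ch.role == "individual":
                chan_truth[:, ci] = t[:, sample_col[ch.sample_id]]
            elif ch.role == "validation_pool":
                chan_truth[:, ci] = pool1
            else:  # bridge / reference
                chan_truth[:, ci] = pool2

        records: list[PsmRecord] = []
        spectrum_counter = 0
        for i in range(cfg.n_proteins):
            intra = intra_target[i]
            blank = intra[1] if (intra is not None and intra[0] == p) else set()
            for seq, charge, fraction in peptides[i]:
                n_psm = 1 + rng.poisson(max(cfg.psms_per_peptide - 1.0, 0.0))
                for _ in range(n_psm):
                    o = cfg.ms1_log2_sd * rng.standard_normal()
                    eps = cfg.tech_sd * rng.standard_normal(design.n_channels)
                    reporters = 2.0 ** (chan_truth[i] + d_k[i] + o + eps)
                    purity = rng.beta(cfg.purity_alpha, cfg.purity_beta)
                    labeled = rng.uniform() >= cfg.frac_unlabeled
                    contam = rng.uniform() < cfg.frac_contaminant
                    razor = rng.uniform() < cfg.frac_razor
                    prob = rng.uniform(0.9, 1.0)
                    if p in drop_plexes[i]:
                        continue  # inter-plex dropout: protein absent from plex
                    rep: list[float | None] = [
                        None if ci in blank else float(reporters[ci])
                        for ci in range(design.n_channels)
                    ]
                    spectrum_counter += 1
                    records.append(
                        PsmRecord(
                            plex_id=design.plex_id,
                            run_id=f"f{fraction + 1}",
                            spectrum_id=f"{design.plex_id}.f{fraction + 1}.{spectrum_counter:06d}",
                            peptide=seq,
                            charge=charge,
                            entry_id=entries[i],
                            assignment="razor" if razor else "unique",
                            is_contaminant=contam,
                            has_tmt_label=labeled,
                            ms1_intensity=float(2.0 ** (beta[i] + d_k[i] + o)),
                            reporter=rep,
                            purity=float(purity),
                            psm_probability=float(prob),
                        )
                    )
        psm_tables[design.plex_id] = records

    realized = _realized_dropout(psm_tables, designs, entries)

    frame = pd.DataFrame(
        {
            "entry_id": entries,
            "true_log2fc": true_fc,
            "is_null": is_null,
            "true_g": true_g,
            "injected_dropout": injected,
            "dropout_class": [realized[e] for e in entries],
            "annotation": annot,
        }
    ).set_index("entry_id")
    truth = GroundTruth(
        frame=frame,
        plex_shifts=pd.DataFrame(
            shifts, index=entries, columns=[d.plex_id for d in designs]
        ),
        sample_truth=pd.DataFrame(t, index=entries, columns=sample_ids),
        pool1_log2=pd.Series(pool1, index=entries),
        pool2_log2=pd.Series(pool2, index=entries),
    )
    return SimResult(psm_tables=psm_tables, designs=designs, clinical=clinical, truth=truth)


def _realized_dropout(
    psm_tables: dict[str, list[PsmRecord]],
    designs: list[PlexDesign],
    entries: list[str],
) -> dict[str, str]:
    """Presence pattern after the quality-filter chain, classified per protein.

    A (protein, channel) cell counts as measured when at least one PSM
    surviving filtering + redundant collapse has a positive reference
    intensity and a nonmissing positive intensity in that channel — exactly
    the cells that reach the ratio matrix.
    """
    measured: dict[str, dict[str, set[int]]] = {e: {} for e in entries}
    n_nonref: dict[str, int] = {}
    for d in designs:
        kept, _ = apply_quality_filters(psm_tables[d.plex_id], d)
        kept = collapse_redundant(kept)
        ref_idx = d.reference_index
        nonref = [ci for ci, c in enumerate(d.channels) if c.role != "reference"]
        n_nonref[d.plex_id] = len(nonref)
        for psm in kept:
            ref = psm.reporter[ref_idx]
            if ref is None or not ref > 0:
                continue
            got = measured.setdefault(psm.entry_id, {}).setdefault(d.plex_id, set())
            for ci in nonref:
                v = psm.reporter[ci]
                if v is not None and not (isinstance(v, float) and np.isnan(v)) and v > 0:
                    got.add(ci)
    out = {}
    for e in entries:
        per_plex = {
            d.plex_id: (len(measured.get(e, {}).get(d.plex_id, set())), n_nonref[d.plex_id])
            for d in designs
        }
        out[e] = _classify_realized(per_plex)
    return out


def truth_summary(gt: GroundTruth) -> pd.DataFrame:
    """Tabular per-protein truth export, joinable to DE/effect outputs."""
    return gt.frame.reset_index()
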