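"""Shared fixtures: a small toy plex and the full-size simulated study.

The full study simulation (4 x 10-plex, 10 CTL vs 22 PDR, default noise) is
expensive enough to share at session scope; tests must not mutate it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from plexbridge import normalize_plexes
from plexbridge.simulate import SimConfig, simulate_experiment
from plexbridge.types import PlexChannel, PlexDesign, PsmRecord


def make_design(plex_id: str = "plex1", n_channels: int = 10) -> PlexDesign:
    """n_channels-plex: individuals in channels 1..n-2, pool1, reference last."""
    channels = [
        PlexChannel(f"ch{j + 1:02d}", f"S{j + 1:02d}", "individual",
                    "CTL" if j % 2 == 0 else "PDR")
        for j in range(n_channels - 2)
    ]
    channels.append(PlexChannel(f"ch{n_channels - 1:02d}", "pool1.1", "validation_pool", "n/a"))
    channels.append(PlexChannel(f"ch{n_channels:02d}", "pool2.1", "reference", "n/a"))
    return PlexDesign(plex_id=plex_id, channels=channels)


def make_psm(
    design: PlexDesign,
    entry: str = "G1",
    reporter=None,
    spectrum: str = "sp1",
    peptide: str = "ACDEFGHIK",
    charge: int = 2,
    run: str = "f1",
    **kw,
) -> PsmRecord:
    if reporter is None:
        reporter = [100.0] * design.n_channels
    return PsmRecord(
        plex_id=design.plex_id,
        run_id=run,
        spectrum_id=spectrum,
        peptide=peptide,
        charge=charge,
        entry_id=entry,
        reporter=list(reporter),
        ms1_intensity=kw.pop("ms1_intensity", 1000.0),
        **kw,
    )


@pytest.fixture(scope="session")
def toy_design() -> PlexDesign:
    return make_design()


@pytest.fixture(scope="session")
def study_sim():
    """Default study-design simulation (4 plexes, 10 CTL / 22 PDR)."""
    return simulate_experiment(SimConfig(seed=1))


@pytest.fixture(scope="session")
def study_pipeline(study_sim):
    """(sim, abundance, normalized ratios, params, reports) for the study run."""
    abundance, rn, params, reports = normalize_plexes(
        study_sim.psm_tables, study_sim.designs
    )
    return study_sim, abundance, rn, params, reports
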