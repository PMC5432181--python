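"""Shared fixtures: small simulated runs reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import dealkit as dk


def preprocess_run(run: dk.SimulatedRun, mode: str) -> tuple[list, dict]:
    """Preprocess every demultiplexed index and pool the pseudo-reads."""
    pseudo, drops = [], {}
    for idx in sorted(run.reads_by_index):
        r1s, r2s = run.reads_by_index[idx]
        res = dk.preprocess_pairs(r1s, r2s, dk.RunConfig(), mode=mode)
        pseudo.extend(res.pseudo_reads)
        for k, v in res.drops.items():
            drops[k] = drops.get(k, 0) + v
    return pseudo, drops


@pytest.fixture(scope="session")
def scfv_clean():
    """Error-free scFv run: 400 uniques, 2400 pairs."""
    cfg = dk.SimulationConfig(
        n_unique=400, n_reads=2400, construct="scfv", rng_seed=11,
        error_spec=dk.ErrorSpec(baseline=0.0, spikes=()),
    )
    rep = dk.generate_repertoire(cfg)
    run = dk.simulate_reads(rep, cfg)
    pseudo, drops = preprocess_run(run, "scfv")
    return {"cfg": cfg, "rep": rep, "run": run, "pseudo": pseudo, "drops": drops}


@pytest.fixture(scope="session")
def vh_flagged():
    """VH run whose substitution errors sit only on flagged cycles.

    Two error spikes: one inside the Phred miscalibration window (visible
    only through the control profile) and one outside it (also visible as
    a low reported quality).
    """
    spec = dk.ErrorSpec(baseline=0.0, spikes=((12, 24, 0.03), (150, 160, 0.02)))
    cfg = dk.SimulationConfig(
        n_unique=600, n_reads=3600, construct="vh", coverage="exact",
        rng_seed=13, error_spec=spec,
    )
    rep = dk.generate_repertoire(cfg)
    run = dk.simulate_reads(rep, cfg)
    ctrl = dk.simulate_phix(cfg, 8000)
    profile = dk.compute_phix_profile(ctrl.reads, ctrl.reference)
    pseudo, drops = preprocess_run(run, "vh")
    return {"cfg": cfg, "rep": rep, "run": run, "pseudo": pseudo,
            "profile": profile, "ctrl": ctrl, "drops": drops}
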