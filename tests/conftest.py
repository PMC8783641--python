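"""Shared fixtures: synthetic sessions reused across test modules."""

import numpy as np
import pytest

import hippolfp as h

PYR_RAD_PROFILES = (
    h.LayerProfile("str_oriens", 40.0, -20.0),
    h.LayerProfile("str_pyramidale", 50.0, 0.0),
    h.LayerProfile("str_radiatum", 60.0, 60.0),
)

LAMINAR_PROFILES = (
    h.LayerProfile("str_pyramidale", 50.0, 0.0),
    h.LayerProfile("str_radiatum", 60.0, 60.0),
    h.LayerProfile("str_LM", 100.0, 180.0),
    h.LayerProfile("dg_moleculare", 80.0, 200.0),
    h.LayerProfile("dg_granule", 60.0, 215.0),
)


@pytest.fixture(scope="session")
def swr_session():
    """600 s immobility-only session with a 0.4 events/s sharp-wave-ripple
    train on a 3-site shank; the workhorse for detector validation."""
    cfg = h.SynthConfig(
        duration_s=600.0, sites_per_shank=3, layer_profiles=PYR_RAD_PROFILES,
        speed_profile=h.SpeedProfile(immobility_s=600.0, locomotion_s=0.0),
        swr_rate_hz=0.4, seed=12345)
    rec, cmap, speed, gt = h.generate_session(cfg)
    return cfg, rec, cmap, speed, gt


@pytest.fixture(scope="session")
def laminar_session():
    """120 s session across five CA1-dentate sites with alternating
    immobility/locomotion bouts and default theta-gamma coupling."""
    cfg = h.SynthConfig(
        duration_s=120.0, sites_per_shank=5, layer_profiles=LAMINAR_PROFILES,
        speed_profile=h.SpeedProfile(immobility_s=30.0, locomotion_s=30.0),
        swr_rate_hz=0.4, seed=7)
    rec, cmap, speed, gt = h.generate_session(cfg)
    return cfg, rec, cmap, speed, gt


@pytest.fixture(scope="session")
def swr_detections(swr_session):
    """Paired SWR detections on the workhorse session."""
    cfg, rec, cmap, speed, gt = swr_session
    imm = h.nominal_immobility(cfg)
    ripples = h.detect_ripples(rec.channel("s0d1"), rec.rate_hz, imm)
    spws = h.detect_spws(rec.channel("s0d2"), rec.rate_hz, imm)
    swrs = h.pair_swr(ripples, spws)
    return imm, ripples, spws, swrs
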