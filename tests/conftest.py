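"""Shared fixtures: small synthetic sessions and record builders."""

from __future__ import annotations

from datetime import datetime, time

import pytest

from lickometry.bout_engine import events_to_log
from lickometry.device_log import DeviceSettings, MinuteRecord
from lickometry.simulator import SimConfig, simulate_session

SESSION_START = datetime(2023, 1, 2, 7, 0)


def make_record(minute: int = 0, cage: int = 1, side: str = "left",
                role: str = "water", **counters) -> MinuteRecord:
    from datetime import timedelta

    return MinuteRecord(
        SESSION_START + timedelta(minutes=minute), cage, side, role, **counters
    )


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Two cages, one day of water drinking; small enough for fast tests."""
    return SimConfig(seed=7, n_cages=2, days=1)


@pytest.fixture(scope="session")
def small_session(small_config):
    """(config, events, truth) for the small water simulation."""
    events, truth = simulate_session(small_config)
    return small_config, events, truth


@pytest.fixture(scope="session")
def small_log(small_session):
    """(config, log, detected_bouts) after full device emulation."""
    cfg, events, truth = small_session
    log, bouts = events_to_log(
        events, cfg.settings(), cfg.session_start,
        n_bins=cfg.days * 86_400 // cfg.bin_size_s,
    )
    return cfg, log, bouts


@pytest.fixture()
def settings() -> DeviceSettings:
    return DeviceSettings()


@pytest.fixture(scope="session")
def paper_scale():
    """Full default water study: 16 cages x 2 bottles x 7 d through the whole
    pipeline (simulate, detect, bin, clean, hourly aggregate)."""
    from lickometry.microstructure import aggregate_bins, clean_minute_bins

    cfg = SimConfig(seed=1)
    events, truth = simulate_session(cfg)
    log, bouts = events_to_log(
        events, cfg.settings(), cfg.session_start,
        n_bins=cfg.days * 86_400 // cfg.bin_size_s,
    )
    cleaned = clean_minute_bins(log.records)
    aggs = aggregate_bins(cleaned, "1h", cfg.settings())
    return cfg, truth, log, cleaned, aggs
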