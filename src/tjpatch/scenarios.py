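"""Named experimental scenarios for the synthetic recording generator.

Each scenario bundles channel classes (gating model + channel count),
a voltage protocol and optional pharmacological block, emulating the
experimental conditions of trans-tight-junction patch-clamp recordings:

* ``cldn2_induced`` / ``cldn2_suppressed`` / ``parental`` — MDCKI
  monolayers with induced, suppressed or absent claudin-2 expression.
  Suppression changes channel *number* (8-fold fewer channels), not
  single-channel gating, so the expected NPo ratio is 1/8.
* ``caco2_control`` / ``caco2_kd`` — the human intestinal line with and
  without claudin-2 knockdown (slightly smaller ~82 pS conductance).
* ``la3_block`` — basolateral La³⁺ abolishes claudin-2 events at once.
* ``mtset_i66c`` — MTSET derivatization of the I66C pore mutant removes
  active channels over ~seconds (detectable events gone within ~20 s).
* ``cooled`` — phenomenological cooling: gating rates and the active
  claudin-2 channel count are scaled down; the ~4 pA independent class
  is cold-resistant and untouched.
* ``off_junction`` — pipette sealed over apical membrane away from the
  junction: only sub-2 pA transmembrane events, more frequent at
  +100 mV than at −100 mV.

``make_scenario`` returns both the rendered trace and the exact
ground-truth event table, so detection and NPo estimates can be tested
against truth.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .gating import (
    GatingModel,
    StatePath,
    claudin2_model,
    concat_paths,
    independent_channel_model,
    off_junction_model,
    simulate_state_path,
)
from .protocol import VoltageProtocol, hold
from .recording import CurrentTrace, RecordingConfig, render_current

__all__ = ["Scenario", "SCENARIO_NAMES", "make_scenario", "truth_npo", "TRUTH_COLUMNS"]

TRUTH_COLUMNS = ["channel_class", "channel_index", "level", "start_s", "duration_s", "amplitude_pA"]

CLDN2_N_INDUCED = 8
CLDN2_N_SUPPRESSED = 1
COOLING_SCALE = 0.63  # rate & channel-count multiplier at 15 °C vs 37 °C

SCENARIO_NAMES = (
    "cldn2_induced",
    "cldn2_suppressed",
    "parental",
    "caco2_control",
    "caco2_kd",
    "la3_block",
    "mtset_i66c",
    "cooled",
    "off_junction",
)


@dataclass(frozen=True)
class Scenario:
    """Channel composition and block settings of a named condition."""

    name: str
    channel_classes: tuple[tuple[str, GatingModel, int], ...]  # (class label, model, count)
    block_onset: float | None = None  # s; claudin-2 channels deactivate after this
    block_timescale: float | None = None  # s; exponential decay of active count (0/None = step)
    temperature_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.name in ("parental", "off_junction"):
            for label, _, n in self.channel_classes:
                if label == "cldn2" and n > 0:
                    raise ValueError(f"{self.name} must not contain claudin-2 channels")


def _scenario(name: str, duration: float) -> Scenario:
    cldn2 = claudin2_model()
    indep = independent_channel_model()
    if name == "cldn2_induced":
        return Scenario(name, (("cldn2", cldn2, CLDN2_N_INDUCED), ("independent", indep, 1)))
    if name == "cldn2_suppressed":
        return Scenario(name, (("cldn2", cldn2, CLDN2_N_SUPPRESSED), ("independent", indep, 1)))
    if name == "parental":
        return Scenario(name, (("cldn2", cldn2, 0), ("independent", indep, 1)))
    if name == "caco2_control":
        m = claudin2_model(conductance_ps=82.0)
        return Scenario(name, (("cldn2", m, CLDN2_N_INDUCED), ("independent", indep, 1)))
    if name == "caco2_kd":
        m = claudin2_model(conductance_ps=82.0)
        return Scenario(name, (("cldn2", m, CLDN2_N_SUPPRESSED), ("independent", indep, 1)))
    if name == "la3_block":
        return Scenario(
            name,
            (("cldn2", cldn2, CLDN2_N_INDUCED), ("independent", indep, 1)),
            block_onset=duration / 2,
            block_timescale=None,
        )
    if name == "mtset_i66c":
        return Scenario(
            name,
            (("cldn2", cldn2, CLDN2_N_INDUCED), ("independent", indep, 1)),
            block_onset=duration / 2,
            block_timescale=7.0,
        )
    if name == "cooled":
        n_active = int(round(COOLING_SCALE * CLDN2_N_INDUCED))
        return Scenario(
            name,
            (("cldn2", cldn2.scaled(COOLING_SCALE), n_active), ("independent", indep, 1)),
            temperature_scale=COOLING_SCALE,
        )
    if name == "off_junction":
        # channel models per half-record are built in make_scenario
        return Scenario(name, (("off_junction", off_junction_model(), 2),))
    raise ValueError(f"unknown scenario {name!r}")


def make_scenario(
    name: str,
    seed: int,
    duration: float | None = None,
    config: RecordingConfig | None = None,
) -> tuple[CurrentTrace, pd.DataFrame]:
    """Generate a scenario trace plus its exact ground-truth event table.

    Returns
    -------
    trace
        The rendered, filtered, noisy current trace.
    truth
        One row per true open sojourn: channel class, channel index,
        level (always 1 per channel), start, duration and the noiseless
        amplitude γ·(V − V_rev)/1000 at the sojourn start.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    if duration is None:
        duration = 40.0 if name in ("la3_block", "mtset_i66c") else 20.0
    if config is None:
        config = RecordingConfig(duration=duration)
    else:
        config = replace(config, duration=duration)

    scen = _scenario(name, duration)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    if name == "off_junction":
        protocol = VoltageProtocol(
            hold(-100.0, duration / 2).segments + hold(100.0, duration / 2).segments
        )
        slow = off_junction_model(tau_closed_s=2.0)  # −100 mV half: sparse openings
        fast = off_junction_model(tau_closed_s=0.5)  # +100 mV half: more frequent
        paths = []
        labels = []
        n = scen.channel_classes[0][2]
        for i in range(n):
            p1 = simulate_state_path(slow, duration / 2, np.random.default_rng(ss.spawn(1)[0]))
            p2 = simulate_state_path(fast, duration / 2, np.random.default_rng(ss.spawn(1)[0]))
            paths.append(concat_paths(p1, p2))
            labels.append(("off_junction", i))
    else:
        protocol = hold(-100.0, duration)
        paths, labels = [], []
        for label, model, n in scen.channel_classes:
            for i in range(n):
                path = simulate_state_path(model, duration, np.random.default_rng(ss.spawn(1)[0]))
                if label == "cldn2" and scen.block_onset is not None:
                    t_off = scen.block_onset
                    if scen.block_timescale:
                        t_off += float(rng.exponential(scen.block_timescale))
                    path = path.truncated(t_off)
                paths.append(path)
                labels.append((label, i))

    render_seed = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
    cfg = replace(config, rng_seed=render_seed)
    trace = render_current(
        paths, protocol, cfg, metadata={"scenario": name, "seed": seed}
    )

    rows = []
    for path, (label, idx) in zip(paths, labels):
        m = path.model
        g_open = max(m.pore_conductance)
        for start, dur in path.open_sojourns():
            v = float(protocol.voltage_at(np.array([start]))[0])
            amp = g_open * (v - m.reversal_potential) / 1000.0
            rows.append((label, idx, 1, start, dur, amp))
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS).sort_values("start_s").reset_index(drop=True)
    return trace, truth


def truth_npo(
    truth: pd.DataFrame,
    total_time: float,
    channel_class: str | None = None,
    after: float = 0.0,
) -> float:
    """NPo implied by a ground-truth event table.

    For the superposition of channels, Σ(level × open time) equals the
    summed per-channel open time, so NPo is the summed true open
    duration divided by the record time.  ``after`` restricts the
    window (e.g. post-block), clipping sojourns at the window edge.
    """
    if total_time <= after:
        raise ValueError("window must have positive length")
    d = truth if channel_class is None else truth[truth["channel_class"] == channel_class]
    start = d["start_s"].to_numpy()
    end = start + d["duration_s"].to_numpy()
    open_time = np.clip(np.minimum(end, total_time) - np.maximum(start, after), 0.0, None).sum()
    return float(open_time / (total_time - after))
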