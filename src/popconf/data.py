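"""Session data model and file I/O.

A recording session is represented by a :class:`SessionBundle`: a trial
table (signed motion coherence, choice, correctness, reaction time,
optional pulse and prior-block annotations), a spike table (neuron id,
trial id, spike time relative to motion onset), and a neuron metadata
table (functional class, cluster slot).

All stored spike times are motion-onset-relative; saccade alignment is
computed on the fly as ``t - rt``. Counting windows are half-open
``[start, end)`` so that counts are additive over adjacent windows.
Sessions round-trip through plain UTF-8 CSV files (``trials.csv``,
``spikes.csv``, ``neurons.csv``), one directory per session.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Signed coherence levels of the random-dot task (leftward positive).
DEFAULT_COHERENCE_SET = (
    0.0, 0.032, 0.064, 0.128, 0.256, 0.512,
    -0.032, -0.064, -0.128, -0.256, -0.512,
)

#: Presaccadic window: the 100 ms epoch ending 50 ms before saccade onset.
PRESACCADIC_WINDOW = (-0.150, -0.050)

TRIAL_COLUMNS = [
    "trial_id", "coherence", "choice", "correct", "rt",
    "pulse_onset", "pulse_direction", "prior_block", "session_id",
]
SPIKE_COLUMNS = ["neuron_id", "trial_id", "spike_time"]
NEURON_COLUMNS = ["neuron_id", "session_id", "neuron_class", "cluster"]

NEURON_CLASSES = ("Tin", "Min_left", "Min_right", "other")


class ValidationError(ValueError):
    """A session bundle violates a structural invariant."""


class EmptySelectionError(ValueError):
    """A trial/neuron filter selected nothing."""


@dataclass
class SessionBundle:
    """Trials + spikes + neuron metadata for one recording session.

    Attributes
    ----------
    trials : pandas.DataFrame
        One row per trial with columns ``trial_id, coherence, choice,
        correct, rt, pulse_onset, pulse_direction, prior_block,
        session_id``. ``choice`` and ``pulse_direction`` take values
        ``{"left", "right"}``; optional columns hold NaN when absent.
    spikes : pandas.DataFrame
        Columns ``neuron_id, trial_id, spike_time`` (seconds from motion
        onset, may be negative), sorted within (neuron, trial).
    neurons : pandas.DataFrame
        Columns ``neuron_id, session_id, neuron_class, cluster``.
    coherence_set : tuple of float
        Declared signed coherence levels.
    """

    trials: pd.DataFrame
    spikes: pd.DataFrame
    neurons: pd.DataFrame
    coherence_set: tuple = DEFAULT_COHERENCE_SET

    def __post_init__(self) -> None:
        self.trials = self.trials.reset_index(drop=True)
        self.neurons = self.neurons.reset_index(drop=True)
        for col in ("pulse_onset", "pulse_direction", "prior_block"):
            if col not in self.trials.columns:
                self.trials[col] = np.nan
        self.spikes = (
            self.spikes.sort_values(["neuron_id", "trial_id", "spike_time"])
            .reset_index(drop=True)
        )

    @property
    def tin_ids(self) -> np.ndarray:
        return self.neurons.loc[
            self.neurons["neuron_class"] == "Tin", "neuron_id"
        ].to_numpy()

    def min_ids(self, side: str) -> np.ndarray:
        return self.neurons.loc[
            self.neurons["neuron_class"] == f"Min_{side}", "neuron_id"
        ].to_numpy()

    def validate(self) -> None:
        """Check all structural invariants; raise ValidationError on failure."""
        t = self.trials
        if (t["rt"] <= 0).any():
            bad = t.loc[t["rt"] <= 0, "trial_id"].iloc[0]
            raise ValidationError(f"trial {bad}: rt must be positive")
        if t["trial_id"].duplicated().any():
            raise ValidationError("duplicate trial_id")
        coh_ok = np.isclose(
            np.abs(t["coherence"].to_numpy())[:, None],
            np.abs(np.asarray(self.coherence_set))[None, :],
        ).any(axis=1)
        if not coh_ok.all():
            bad = t.loc[~coh_ok, "trial_id"].iloc[0]
            raise ValidationError(f"trial {bad}: coherence outside declared set")
        nonzero = t["coherence"] != 0
        want_left = t["coherence"] > 0
        consistent = t["correct"] == (want_left == (t["choice"] == "left"))
        if (nonzero & ~consistent).any():
            bad = t.loc[nonzero & ~consistent, "trial_id"].iloc[0]
            raise ValidationError(
                f"trial {bad}: correctness inconsistent with coherence sign and choice"
            )
        known_trials = set(t["trial_id"])
        known_neurons = set(self.neurons["neuron_id"])
        sp_trials = set(self.spikes["trial_id"].unique())
        if not sp_trials <= known_trials:
            bad = sorted(sp_trials - known_trials)[0]
            raise ValidationError(f"spike references unknown trial {bad}")
        sp_neurons = set(self.spikes["neuron_id"].unique())
        if not sp_neurons <= known_neurons:
            bad = sorted(sp_neurons - known_neurons)[0]
            raise ValidationError(f"spike references unknown neuron {bad}")
        if self.neurons["neuron_id"].duplicated().any():
            raise ValidationError("duplicate neuron_id")
        has_cluster = self.neurons["cluster"].notna()
        not_tin = self.neurons["neuron_class"] != "Tin"
        if (has_cluster & not_tin).any():
            bad = self.neurons.loc[has_cluster & not_tin, "neuron_id"].iloc[0]
            raise ValidationError(f"neuron {bad}: cluster set for non-Tin neuron")
        if len(self.spikes):
            rt_map = t.set_index("trial_id")["rt"]
            st = self.spikes["spike_time"].to_numpy()
            rts = rt_map.loc[self.spikes["trial_id"]].to_numpy()
            if (st < -1.0 - 1e-9).any() or (st > rts + 0.5 + 1e-9).any():
                raise ValidationError("spike time outside [-1, rt + 0.5]")

    def subset_trials(self, trial_ids: Iterable[int]) -> "SessionBundle":
        ids = np.asarray(list(trial_ids))
        return SessionBundle(
            trials=self.trials[self.trials["trial_id"].isin(ids)].copy(),
            spikes=self.spikes[self.spikes["trial_id"].isin(ids)].copy(),
            neurons=self.neurons.copy(),
            coherence_set=self.coherence_set,
        )


@dataclass
class CountMatrix:
    """Trials x neurons spike-count matrix for one counting window.

    ``values[i, j]`` is the count (or standardized count) of neuron
    ``neuron_ids[j]`` on trial ``trial_ids[i]`` in the half-open window
    ``[window[0], window[1])`` under the declared alignment.
    """

    values: np.ndarray
    window: tuple
    alignment: str
    trial_ids: np.ndarray
    neuron_ids: np.ndarray
    standardized: bool = False

    def standardize(self) -> "CountMatrix":
        """Z-score each column over included trials (idempotent)."""
        v = np.asarray(self.values, dtype=float)
        mu = v.mean(axis=0)
        sd = v.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        return replace(self, values=(v - mu) / sd, standardized=True)

    def column(self, neuron_id: int) -> np.ndarray:
        j = int(np.flatnonzero(self.neuron_ids == neuron_id)[0])
        return self.values[:, j]


def _read_csv(path: Path, name: str) -> pd.DataFrame:
    f = path / name
    if not f.exists():
        raise FileNotFoundError(f"missing session file: {f}")
    return pd.read_csv(f)


def load_session(path) -> SessionBundle:
    """Load a validated session bundle from a directory of CSV files."""
    path = Path(path)
    trials = _read_csv(path, "trials.csv")
    spikes = _read_csv(path, "spikes.csv")
    neurons = _read_csv(path, "neurons.csv")
    trials["correct"] = trials["correct"].astype(bool)
    meta_f = path / "coherences.csv"
    if meta_f.exists():
        coh = tuple(pd.read_csv(meta_f)["coherence"].tolist())
    else:
        coh = DEFAULT_COHERENCE_SET
    bundle = SessionBundle(trials, spikes, neurons, coherence_set=coh)
    bundle.validate()
    return bundle


def write_session(bundle: SessionBundle, path) -> Path:
    """Write a bundle to a session directory; deterministic row order."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    trials = bundle.trials.sort_values("trial_id")
    trials.to_csv(path / "trials.csv", index=False)
    spikes = bundle.spikes.sort_values(["neuron_id", "trial_id", "spike_time"])
    spikes.to_csv(path / "spikes.csv", index=False)
    neurons = bundle.neurons.sort_values("neuron_id")
    neurons.to_csv(path / "neurons.csv", index=False)
    pd.DataFrame({"coherence": list(bundle.coherence_set)}).to_csv(
        path / "coherences.csv", index=False
    )
    return path


def extract_counts(
    bundle: SessionBundle,
    window: Sequence[float],
    alignment: str = "motion_onset",
    neuron_filter: Iterable[int] | None = None,
    trial_filter: Iterable[int] | None = None,
    standardize: bool = False,
) -> CountMatrix:
    """Count spikes per (trial, neuron) in a half-open window.

    Parameters
    ----------
    window : (start, end)
        Half-open interval in seconds. A spike at exactly ``end`` is not
        counted.
    alignment : {"motion_onset", "saccade"}
        Under ``"saccade"`` spike times are re-referenced to ``t - rt``.
    neuron_filter, trial_filter : optional iterables of ids
        Restrict the matrix; default all neurons / all trials.
    """
    start, end = float(window[0]), float(window[1])
    if not start < end:
        raise ValueError("window start must be < end")
    if alignment not in ("motion_onset", "saccade"):
        raise ValueError(f"unknown alignment: {alignment}")

    trial_ids = (
        np.asarray(sorted(set(trial_filter)))
        if trial_filter is not None
        else np.sort(bundle.trials["trial_id"].to_numpy())
    )
    neuron_ids = (
        np.asarray(sorted(set(neuron_filter)))
        if neuron_filter is not None
        else np.sort(bundle.neurons["neuron_id"].to_numpy())
    )
    if len(trial_ids) == 0 or len(neuron_ids) == 0:
        raise EmptySelectionError("empty trial or neuron selection")

    sp = bundle.spikes
    sp = sp[sp["trial_id"].isin(trial_ids) & sp["neuron_id"].isin(neuron_ids)]
    t = sp["spike_time"].to_numpy()
    if alignment == "saccade":
        rt_map = bundle.trials.set_index("trial_id")["rt"]
        t = t - rt_map.loc[sp["trial_id"]].to_numpy()
    in_win = (t >= start) & (t < end)
    sp = sp[in_win]

    ti = pd.Categorical(sp["trial_id"], categories=trial_ids).codes
    ni = pd.Categorical(sp["neuron_id"], categories=neuron_ids).codes
    values = np.zeros((len(trial_ids), len(neuron_ids)))
    np.add.at(values, (ti, ni), 1.0)

    cm = CountMatrix(
        values=values,
        window=(start, end),
        alignment=alignment,
        trial_ids=trial_ids,
        neuron_ids=neuron_ids,
        standardized=False,
    )
    return cm.standardize() if standardize else cm
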