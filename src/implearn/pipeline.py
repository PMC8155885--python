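"""Glue: raw recording + events -> labeled entropy-feature table.

Chains the stages in their canonical order: condition the recording
(band-pass + notch), split it into frequency bands, cut per-question
epochs, compute a multiscale-entropy profile per epoch, label trials
fast/slow from response times, balance the classes, and assemble the
classifier table.  Each stage remains available individually for
custom workflows; this module is the one-call path the examples and
the command line use.
"""

from __future__ import annotations

import logging

import pandas as pd

from .entropy import SampEnParams, mse_profile
from .features import FeatureSpace, FeatureTable, assemble
from .io import DEFAULT_BANDS, EventTable, Recording, band_split, bandpass_notch, epoch_recording
from .labeling import balance_classes, label_trials

logger = logging.getLogger(__name__)

__all__ = ["extract_profiles", "build_table"]


def extract_profiles(
    rec: Recording,
    events: EventTable,
    bands: dict[str, tuple[float, float]] | None = None,
    channels: list[str] | None = None,
    params: SampEnParams | None = None,
    tau_max: int = 20,
    question: int | None = None,
    low: float = 0.5,
    high: float = 50.0,
    notch: float | None = 60.0,
) -> pd.DataFrame:
    """Filter, band-split, epoch and compute MSE profiles.

    Returns the long-format profile frame (trial, question, channel,
    band, scale, sampen, n_points, r_abs).  ``question`` restricts the
    computation to one question's epochs (None = all four);
    ``channels`` restricts to a channel subset.  ``notch=None`` skips
    the power-line notch (pointless below a 120 Hz sampling rate).
    """
    params = params or SampEnParams()
    filtered = bandpass_notch(rec, low=low, high=high, notch=notch)
    per_band = band_split(filtered, bands or dict(DEFAULT_BANDS))
    keep = set(channels) if channels is not None else set(rec.channel_names)
    rows = []
    for band, brec in per_band.items():
        for ep in epoch_recording(brec, events, band=band):
            if ep.channel not in keep:
                continue
            if question is not None and ep.question != question:
                continue
            prof = mse_profile(ep, params, tau_max)
            for tau in range(1, tau_max + 1):
                rows.append({
                    "trial": ep.trial, "question": ep.question,
                    "channel": ep.channel, "band": band, "scale": tau,
                    "sampen": prof.values[tau - 1],
                    "n_points": prof.n_points[tau - 1],
                    "r_abs": prof.r_abs,
                })
    return pd.DataFrame(rows)


def build_table(
    rec: Recording,
    events: EventTable,
    space: FeatureSpace | None = None,
    bands: dict[str, tuple[float, float]] | None = None,
    params: SampEnParams | None = None,
    tau_max: int = 20,
    question: int = 4,
    reduce: str | None = None,
    balance_seed: int = 0,
    notch: float | None = 60.0,
) -> FeatureTable:
    """Recording + events -> balanced, labeled feature table.

    The feature space defaults to the nine frontal channels and five
    clinical bands; pass a smaller space (and matching ``bands``) for
    reduced setups.  Labels come from the TRT rule; classes are
    balanced by seeded down-sampling before assembly.
    """
    space = space or FeatureSpace()
    if bands is None:
        bands = {b: DEFAULT_BANDS[b] for b in space.bands}
    labels = label_trials(events)
    labels = balance_classes(labels, seed=balance_seed)
    profiles = extract_profiles(rec, events, bands=bands,
                                channels=list(space.channels), params=params,
                                tau_max=tau_max, question=question, notch=notch)
    table = assemble(profiles, labels, space=space, tau_max=tau_max,
                     question=question, reduce=reduce)
    # rows dropped for undefined entropy can unbalance the classes;
    # re-balance so the equal-count contract holds downstream
    counts = table.y.value_counts()
    if counts.nunique() > 1:
        relabeled = balance_classes(
            table.y.rename("label").reset_index(drop=True).to_frame(),
            seed=balance_seed)
        keep = table.y.index[relabeled.index]
        table = FeatureTable(X=table.X.loc[keep], y=table.y.loc[keep],
                             space=table.space, tau_max=table.tau_max,
                             reduce=table.reduce)
    return table
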