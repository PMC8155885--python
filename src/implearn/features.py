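"""Feature-table assembly and the binary selection encoding.

The classifier features are multiscale-entropy profiles of the nine
frontal channels (AF3, AF4, F3, F4, F5, F6, F7, F8, FZ) in the five
clinical bands (gamma, beta, alpha, delta, theta): one selection bit per
(channel, band) pair, d = 45 bits under the defaults, each bit gating
that pair's full profile over scales 1..tau_max (45 x 20 = 900 columns).
A bit vector over this space is the "food source" the bee-colony
optimizer searches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError

logger = logging.getLogger(__name__)

__all__ = ["FRONTAL_CHANNELS", "BAND_ORDER", "FeatureSpace", "FeatureTable",
           "assemble", "mask_features"]

FRONTAL_CHANNELS = ("AF3", "AF4", "F3", "F4", "F5", "F6", "F7", "F8", "FZ")
BAND_ORDER = ("gamma", "beta", "alpha", "delta", "theta")


@dataclass(frozen=True)
class FeatureSpace:
    """Ordered (channel, band) feature pairs; channel-major order."""

    channels: tuple[str, ...] = FRONTAL_CHANNELS
    bands: tuple[str, ...] = BAND_ORDER

    def __post_init__(self):
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "bands", tuple(self.bands))

    @property
    def features(self) -> list[tuple[str, str]]:
        return [(ch, b) for ch in self.channels for b in self.bands]

    @property
    def d(self) -> int:
        return len(self.channels) * len(self.bands)


@dataclass
class FeatureTable:
    """Rows = labeled trials, columns = per-scale entropy values.

    ``X`` columns are named ``{channel}_{band}_s{scale}`` (or
    ``..._mean`` when profiles are reduced); ``y`` holds the fast/slow
    labels aligned with ``X``'s index.
    """

    X: pd.DataFrame = field(repr=False)
    y: pd.Series = field(repr=False)
    space: FeatureSpace
    tau_max: int
    reduce: str | None = None

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def d(self) -> int:
        return self.space.d

    def columns_for(self, channel: str, band: str) -> list[str]:
        if self.reduce == "mean":
            return [f"{channel}_{band}_mean"]
        return [f"{channel}_{band}_s{s}" for s in range(1, self.tau_max + 1)]

    def class_counts(self) -> dict[str, int]:
        return self.y.value_counts().to_dict()


def _profile_frame(profiles) -> pd.DataFrame:
    if isinstance(profiles, pd.DataFrame):
        return profiles
    raise ParameterError("profiles must be a long-format DataFrame with columns "
                         "trial, question, channel, band, scale, sampen")


def assemble(profiles: pd.DataFrame, labels: pd.DataFrame,
             space: FeatureSpace | None = None, tau_max: int = 20,
             question: int = 4, reduce: str | None = None) -> FeatureTable:
    """Join entropy profiles with trial labels into a classifier table.

    ``profiles`` is long-format (trial, question, channel, band, scale,
    sampen); ``labels`` has columns trial and label.  By default only
    the fourth question's epochs feed the table (the question governed
    by the hidden rule); ``question=None`` concatenates all four.
    ``reduce="mean"`` collapses each profile to its scale-mean.  Rows
    containing undefined (NaN) entropy values are dropped with a logged
    count; excluded trials never enter.
    """
    space = space or FeatureSpace()
    prof = _profile_frame(profiles)
    if question is not None:
        prof = prof[prof["question"] == question]
    labeled = labels[labels["label"].isin(["fast", "slow"])][["trial", "label"]]

    wide = prof.pivot_table(index="trial", columns=["channel", "band", "scale"],
                            values="sampen", dropna=False)
    expected = [(ch, b, s) for ch, b in space.features
                for s in range(1, tau_max + 1)]
    missing = [c for c in expected if c not in wide.columns]
    if missing:
        raise ParameterError(
            f"profiles missing {len(missing)} (channel, band, scale) entries, "
            f"first: {missing[:3]}"
        )
    wide = wide[expected]
    wide.columns = [f"{ch}_{b}_s{s}" for ch, b, s in expected]
    if reduce == "mean":
        means = {}
        for ch, b in space.features:
            cols = [f"{ch}_{b}_s{s}" for s in range(1, tau_max + 1)]
            means[f"{ch}_{b}_mean"] = wide[cols].mean(axis=1)
        wide = pd.DataFrame(means, index=wide.index)
    elif reduce is not None:
        raise ParameterError(f"unknown reduce mode {reduce!r}")

    wide = wide.loc[wide.index.intersection(labeled["trial"])]
    missing_trials = set(labeled["trial"]) - set(wide.index)
    if missing_trials:
        raise ParameterError(
            f"no profiles for labeled trials {sorted(missing_trials)[:5]}"
        )
    nan_rows = wide.isna().any(axis=1)
    if nan_rows.any():
        logger.info("assemble: dropping %d rows with undefined entropy values",
                    int(nan_rows.sum()))
        wide = wide[~nan_rows]
    lab = labeled.set_index("trial")["label"].loc[wide.index]
    return FeatureTable(X=wide, y=lab, space=space, tau_max=tau_max, reduce=reduce)


def mask_features(table: FeatureTable, bits: np.ndarray) -> FeatureTable:
    """Restrict the table to features whose selection bit is 1.

    ``bits`` is a 0/1 vector over the (channel, band) pairs of the
    table's space, in channel-major order; all scale columns of a
    retained pair are kept, in their original order.  An all-zero vector
    yields a zero-column table (the optimizer's fitness treats that as
    an unclassifiable empty selection).
    """
    bits = np.asarray(bits).ravel()
    if bits.size != table.space.d:
        raise ParameterError(
            f"bit vector length {bits.size} != feature count {table.space.d}"
        )
    present = set(table.X.columns)
    cols: list[str] = []
    for bit, (ch, b) in zip(bits, table.space.features):
        if bit:
            # intersect with present columns so masking is idempotent
            cols.extend(c for c in table.columns_for(ch, b) if c in present)
    return FeatureTable(X=table.X[cols], y=table.y, space=table.space,
                        tau_max=table.tau_max, reduce=table.reduce)
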