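"""Complementary-pairs stability selection with a PFER budget.

Feature selection is stabilized by refitting the boosting learner on many
random half-samples: for each of B complementary pairs the sample index
set is split into two disjoint halves, the learner runs on each half
until ``q`` distinct features have entered the model, and a feature's
selection frequency is its proportion over the 2B runs. Features whose
frequency reaches the cutoff ``pi_thr`` are selected. The three control
parameters (q, cutoff, PFER — the expected number of falsely selected
features) are linked by an error bound; the user fixes two and the third
is derived. Two bounds are available: the original Meinshausen-Buhlmann
bound PFER <= q^2 / ((2*cutoff - 1) * p), and the sharper Shah-Samworth
bound for unimodal selection-probability distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .betaboost import _boost_core, _standardize, _validate_xy


@dataclass(frozen=True)
class StabilityConfig:
    """Controls for complementary-pairs stability selection.

    Exactly two of ``q`` (per-run selection count), ``pfer`` (expected
    false positives) and ``cutoff`` (selection-frequency threshold) should
    be set by the user; :func:`derive_threshold` fills the third.
    """

    B: int = 50
    q: int | None = None
    pfer: float | None = 1.0
    cutoff: float | None = 0.75
    bound: str = "MB"
    seed: int = 0
    nu: float = 0.1

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.bound not in ("MB", "SS-unimodal"):
            raise ValueError(f"unknown bound {self.bound!r}")
        n_set = sum(v is not None for v in (self.q, self.pfer, self.cutoff))
        if n_set < 2:
            raise ValueError(
                "set at least two of q, pfer, cutoff; the third is derived"
            )


@dataclass(frozen=True)
class StabilityResult:
    """Selection frequencies over 2B half-sample runs."""

    frequencies: dict[str, float]
    selected: list[str]
    config: StabilityConfig

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "feature": list(self.frequencies),
                "frequency": list(self.frequencies.values()),
            }
        )
        frame["selected"] = frame["feature"].isin(self.selected)
        return frame


def _pfer_bound(q: int, cutoff: float, p: int, B: int, bound: str) -> float:
    """Upper bound on the expected number of false selections."""
    if bound == "MB":
        return q * q / ((2.0 * cutoff - 1.0) * p)
    # Shah-Samworth bound under unimodal selection probabilities
    if cutoff <= 0.75:
        return q * q / (p * 2.0 * (2.0 * cutoff - 1.0 - 1.0 / (2.0 * B)))
    return 4.0 * (1.0 - cutoff + 1.0 / (2.0 * B)) * q * q / ((1.0 + 1.0 / B) * p)


def derive_threshold(config: StabilityConfig, p: int) -> StabilityConfig:
    """Fill in whichever of q / pfer / cutoff the user left unset.

    Uses the configured error bound; with the default MB bound the
    relation is ``pfer >= q^2 / ((2*cutoff - 1) * p)``, so e.g. for a
    given budget and cutoff the per-run count is
    ``q = floor(sqrt(pfer * (2*cutoff - 1) * p))``.
    """
    if p <= 0:
        raise ValueError("p must be > 0")
    q, pfer, cutoff = config.q, config.pfer, config.cutoff
    if q is not None and pfer is not None and cutoff is not None:
        return config
    if q is None:
        if not 0.5 < cutoff <= 1.0:
            raise ValueError("cutoff must lie in (0.5, 1]")
        # invert the bound for q (monotone increasing in q): largest q with
        # bound(q) <= pfer
        q_val = 0
        while _pfer_bound(q_val + 1, cutoff, p, config.B, config.bound) <= pfer:
            q_val += 1
            if q_val >= p:
                break
        if q_val == 0:
            raise ValueError(
                "PFER budget too small for this cutoff; increase pfer or cutoff"
            )
        return replace(config, q=q_val)
    if pfer is None:
        if not 0.5 < cutoff <= 1.0:
            raise ValueError("cutoff must lie in (0.5, 1]")
        return replace(config, pfer=_pfer_bound(q, cutoff, p, config.B,
                                                config.bound))
    # derive cutoff: smallest threshold in (0.5, 1] meeting the budget
    if config.bound == "MB":
        cutoff_val = (q * q / (pfer * p) + 1.0) / 2.0
    else:
        # solve the SS-unimodal bound numerically on a fine grid
        grid = np.linspace(0.5001, 1.0, 5000)
        ok = [c for c in grid if _pfer_bound(q, c, p, config.B, "SS-unimodal")
              <= pfer]
        if not ok:
            raise ValueError(
                "derived cutoff would exceed 1; change q or pfer"
            )
        cutoff_val = float(ok[0])
    if not 0.5 < cutoff_val <= 1.0:
        raise ValueError(
            f"derived cutoff {cutoff_val:.3f} outside (0.5, 1]; "
            "change q or pfer"
        )
    return replace(config, cutoff=cutoff_val)


def complementary_pairs(rng: np.random.Generator, n: int, B: int):
    """Yield B disjoint half-sample pairs of size floor(n/2) each.

    For odd n one random sample per pair sits in neither half.
    """
    half = n // 2
    for _ in range(B):
        perm = rng.permutation(n)
        yield perm[:half], perm[half: 2 * half]


def run_stability(
    X: pd.DataFrame,
    y,
    config: StabilityConfig,
) -> StabilityResult:
    """Run complementary-pairs stability selection with the boosting learner.

    Each of the B pairs splits a random even-sized subset of the samples
    into two disjoint halves of size floor(n/2); on each half the boosting
    learner runs until ``q`` distinct features have entered (capped at
    10*q iterations). Frequencies are proportions over the 2B runs and
    are deterministic given the seed.
    """
    y = _validate_xy(X, y)
    n, p = X.shape
    if n < 4:
        raise ValueError("need at least 4 samples")
    config = derive_threshold(config, p)
    if config.q >= p:
        raise ValueError("q must be smaller than the number of features")
    rng = np.random.default_rng(config.seed)
    counts = {name: 0 for name in X.columns}
    for halves in complementary_pairs(rng, n, config.B):
        for idx in halves:
            X_half = X.iloc[idx]
            try:
                Xs, cols, _ = _standardize(X_half)
            except ValueError:
                continue
            *_, entered = _boost_core(
                Xs, y[idx], nu=config.nu,
                mstop=10 * config.q, q_stop=config.q,
            )
            for j in entered:
                counts[cols[j]] += 1
    total_runs = 2 * config.B
    frequencies = {name: counts[name] / total_runs for name in X.columns}
    selected = [
        name for name in X.columns if frequencies[name] >= config.cutoff
    ]
    return StabilityResult(
        frequencies=frequencies, selected=selected, config=config
    )


def write_report(result: StabilityResult, csv_path: str,
                 json_path: str | None = None) -> None:
    """Write the ``feature,frequency,selected`` CSV and a config sidecar."""
    result.to_frame().to_csv(csv_path, index=False)
    if json_path is not None:
        import json

        cfg = result.config
        with open(json_path, "w") as fh:
            json.dump(
                {
                    "B": cfg.B, "q": cfg.q, "pfer": cfg.pfer,
                    "cutoff": cfg.cutoff, "bound": cfg.bound,
                    "seed": cfg.seed, "nu": cfg.nu,
                },
                fh, indent=2,
            )
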