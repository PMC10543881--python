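"""Synthetic cfDNA cohorts with the statistical structure the method assumes.

The generator produces everything the pipeline consumes — fragment-length
histograms, panel mutation tables, surrogate labels, manifests — from a
parametric model of plasma cfDNA:

* the **healthy** fragment-length density is a two-component truncated
  normal mixture (mono-nucleosome peak at 166 bp, di-nucleosome peak at
  332 bp) with a 10 bp cosine oscillation on the sub-nucleosomal side of
  each peak;
* the **tumour** density is shifted towards shorter fragments (peaks at
  145 and 300 bp) with a stronger oscillation, so the short-fragment
  windows carry real signal about the tumour fraction;
* a sample with tumour fraction ``theta`` draws its fragments from the
  mixture ``(1 - theta) * healthy + theta * tumour``;
* clonal panel mutations are heterozygous in copy-number-neutral regions,
  so their alt counts are Binomial(depth, theta / 2); a minority of
  subclonal mutations sit at theta / 4;
* surrogate labels are the true fraction perturbed by logit-normal noise,
  mimicking an imperfect external copy-number estimator.

Every sample gets its own child seed spawned from the global seed, so
cohorts are reproducible sample-by-sample.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .io_profiles import LengthHistogram, write_histogram
from .labels import MutationCall, write_mutations


@dataclass(frozen=True)
class ComponentSpec:
    """Two-peak truncated-normal mixture for one tissue component."""

    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    amplitude: float

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9 or min(self.weights) <= 0:
            raise ValueError("weights must be positive and sum to 1")
        if not 0 <= self.amplitude < 1:
            raise ValueError("amplitude must lie in [0, 1)")


@dataclass(frozen=True)
class SimConfig:
    """Defaults describe a stage-IV-like plasma cohort."""

    support: tuple[int, int] = (50, 400)
    healthy: ComponentSpec = field(
        default_factory=lambda: ComponentSpec(
            means=(166.0, 332.0), sds=(9.0, 20.0),
            weights=(0.88, 0.12), amplitude=0.05,
        )
    )
    tumour: ComponentSpec = field(
        default_factory=lambda: ComponentSpec(
            means=(145.0, 300.0), sds=(12.0, 25.0),
            weights=(0.90, 0.10), amplitude=0.15,
        )
    )
    oscillation_period: float = 10.0
    n_fragments: int = 500_000
    depth: int = 600
    surrogate_noise_sd: float = 0.5
    nonannotated_fraction: float = 0.2
    density_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.oscillation_period <= 0:
            raise ValueError("oscillation period must be > 0")


@dataclass(frozen=True)
class SyntheticSample:
    sample_id: str
    theta: float
    histogram: LengthHistogram
    cohort: str                         # "A" | "B" | "dilution"
    mutations: list[MutationCall] | None = None
    surrogate_label: float | None = None
    concentration: float | None = None


def component_density(component: ComponentSpec, config: SimConfig) -> np.ndarray:
    """Discrete fragment-length density of one tissue component.

    Each truncated-normal peak is modulated on its short side
    (``l < mean``) by ``1 + amplitude * cos(2*pi*(mean - l)/period)``,
    a uniform floor is added, and the result is renormalized to sum to
    one over the support grid.
    """
    lo, hi = config.support
    lengths = np.arange(lo, hi + 1, dtype=float)
    total = np.zeros_like(lengths)
    for mean, sd, weight in zip(
        component.means, component.sds, component.weights
    ):
        peak = norm.pdf(lengths, loc=mean, scale=sd)
        peak /= peak.sum()  # truncate + discretize on the support
        modulation = np.where(
            lengths < mean,
            1.0 + component.amplitude
            * np.cos(2.0 * np.pi * (mean - lengths) / config.oscillation_period),
            1.0,
        )
        total += weight * peak * modulation
    total += config.density_floor
    return total / total.sum()


def mixture_density(theta: float, config: SimConfig) -> np.ndarray:
    """Fragment-length density at tumour fraction theta."""
    healthy = component_density(config.healthy, config)
    tumour = component_density(config.tumour, config)
    return (1.0 - theta) * healthy + theta * tumour


def simulate_sample(
    theta: float,
    config: SimConfig = SimConfig(),
    seed: int | np.random.SeedSequence = 0,
    sample_id: str = "sample",
    cohort: str = "A",
) -> SyntheticSample:
    """Draw one synthetic plasma sample at tumour fraction ``theta``.

    Cohort "A" samples additionally carry a panel mutation table
    (1 + Poisson(4) clonal mutations at VAF theta/2, up to three
    subclonal ones at theta/4, all copy-number neutral); cohort "B"
    samples carry a noisy surrogate label; "dilution" samples carry the
    histogram only.
    """
    if not 0.0 <= theta < 1.0:
        raise ValueError("theta must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    lo, _ = config.support
    density = mixture_density(theta, config)
    counts = rng.multinomial(config.n_fragments, density)
    histogram = LengthHistogram(
        sample_id=sample_id,
        counts={lo + i: int(c) for i, c in enumerate(counts) if c > 0},
        support=config.support,
    )
    mutations = None
    surrogate = None
    if cohort == "A":
        n_clonal = 1 + rng.poisson(4)
        n_subclonal = int(rng.integers(0, 4))
        mutations = []
        for k in range(n_clonal + n_subclonal):
            vaf = theta / 2.0 if k < n_clonal else theta / 4.0
            mutations.append(
                MutationCall(
                    sample_id=sample_id,
                    chrom="chr1",
                    pos=1_000_000 + 1000 * k,
                    alt_count=int(rng.binomial(config.depth, vaf)),
                    depth=config.depth,
                    cn_neutral=True,
                    annotated=bool(
                        rng.random() >= config.nonannotated_fraction
                    ),
                )
            )
    elif cohort == "B":
        noisy = expit(logit(theta) + rng.normal(0.0, config.surrogate_noise_sd))
        surrogate = float(np.clip(noisy, 1e-3, 1.0 - 1e-3))
    elif cohort != "dilution":
        raise ValueError(f"unknown cohort {cohort!r}")
    return SyntheticSample(
        sample_id=sample_id,
        theta=float(theta),
        histogram=histogram,
        cohort=cohort,
        mutations=mutations,
        surrogate_label=surrogate,
    )


#: tumour-fraction law for simulated patients (stage-IV-like, mostly > 0.1)
THETA_BETA_PARAMS = (2.0, 3.5)


def simulate_cohorts(
    nA: int = 41,
    nB: int = 71,
    config: SimConfig = SimConfig(),
    seed: int = 0,
) -> list[SyntheticSample]:
    """Simulate the two training cohorts.

    Cohort A (panel-labelled) and cohort B (surrogate-labelled) tumour
    fractions are both drawn from Beta(2.0, 3.5).
    """
    root = np.random.SeedSequence(seed)
    theta_rng = np.random.default_rng(root.spawn(1)[0])
    children = root.spawn(nA + nB)
    a, b = THETA_BETA_PARAMS
    samples = []
    for i in range(nA):
        theta = float(theta_rng.beta(a, b))
        samples.append(
            simulate_sample(
                theta, config, seed=children[i],
                sample_id=f"A{i + 1:03d}", cohort="A",
            )
        )
    for i in range(nB):
        theta = float(theta_rng.beta(a, b))
        samples.append(
            simulate_sample(
                theta, config, seed=children[nA + i],
                sample_id=f"B{i + 1:03d}", cohort="B",
            )
        )
    return samples


def simulate_dilution(
    theta_patient: float = 0.6,
    concentrations: tuple[float, ...] = (0.0, 0.05, 0.1, 0.25, 0.5, 1.0),
    config: SimConfig = SimConfig(),
    seed: int = 0,
) -> list[SyntheticSample]:
    """Simulate a spike-in dilution series of one patient into control plasma.

    Sample at concentration ``c`` has true tumour fraction
    ``c * theta_patient``.
    """
    if any(c < 0 or c > 1 for c in concentrations):
        raise ValueError("concentrations must lie in [0, 1]")
    children = np.random.SeedSequence(seed).spawn(len(concentrations))
    samples = []
    for i, (c, child) in enumerate(zip(concentrations, children)):
        sample = simulate_sample(
            c * theta_patient, config, seed=child,
            sample_id=f"D{i + 1:02d}", cohort="dilution",
        )
        samples.append(
            SyntheticSample(
                sample_id=sample.sample_id,
                theta=sample.theta,
                histogram=sample.histogram,
                cohort="dilution",
                concentration=float(c),
            )
        )
    return samples


def write_samples(samples: list[SyntheticSample], outdir: str) -> str:
    """Write histograms, mutation tables and the cohort manifest.

    Returns the manifest path. The manifest columns are
    ``sample_id,histogram_path,label_source,label_value_or_mutation_path``
    with label_source one of panel / surrogate / concentration / none.
    A ground-truth ``truth.csv`` (sample_id, theta) is written alongside
    for testing only; the pipeline never reads it.
    """
    os.makedirs(outdir, exist_ok=True)
    rows = []
    for sample in samples:
        hist_path = os.path.join(outdir, f"{sample.sample_id}.hist.tsv")
        write_histogram(sample.histogram, hist_path)
        if sample.cohort == "A":
            mut_path = os.path.join(outdir, f"{sample.sample_id}.muts.tsv")
            write_mutations(sample.mutations, mut_path)
            source, value = "panel", mut_path
        elif sample.cohort == "B":
            source, value = "surrogate", repr(sample.surrogate_label)
        elif sample.concentration is not None:
            source, value = "concentration", repr(sample.concentration)
        else:
            source, value = "none", ""
        rows.append(
            {
                "sample_id": sample.sample_id,
                "histogram_path": hist_path,
                "label_source": source,
                "label_value_or_mutation_path": value,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest_path = os.path.join(outdir, "manifest.csv")
    manifest.to_csv(manifest_path, index=False)
    truth = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "theta": [s.theta for s in samples],
        }
    )
    truth.to_csv(os.path.join(outdir, "truth.csv"), index=False)
    return manifest_path
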