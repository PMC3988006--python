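"""Seeded synthetic gene universes with a planted core-clock class.

The generators emulate the five heterogeneous data sources the ranking method
integrates: tissue time-course expression (three tissues, 48 h at 2-h
sampling), an RNAi-screen table of period/amplitude log-ratios (two siRNA
pools per gene), an undirected genetic-interaction edge list, tissue-ubiquity
EST counts, and a Boolean fly-homology flag.  A small planted positive class
("clock genes") has each feature distribution stochastically shifted toward
clock-like values by configurable effect sizes; everything is a pure function
of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .rhythm import cosinor_pvalues

CLOCK_LABEL = "Cgene"
NONCLOCK_LABEL = "NCgene"

# independent RNG stream ids, one per generator
_STREAM_LABELS = 0
_STREAM_TIMECOURSE = 1
_STREAM_SCREEN = 2
_STREAM_NETWORK = 3
_STREAM_UBIQUITY = 4
_STREAM_HOMOLOGY = 5


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic gene universe.

    Effect sizes are expressed on the natural scale of each feature: the
    cycling amplitude is in expression units relative to ``cycling_noise_sd``,
    the screen disturbance shift is in units of the per-pool noise SD, edge
    probabilities are Bernoulli rates, ubiquity counts are Poisson means, and
    homology is a per-class Bernoulli probability.
    """

    n_genes: int = 1000
    n_clock: int = 17
    seed: int = 0

    # time-course design: 24 samples spanning 48 h at 2-h spacing, 3 tissues
    baseline_expression: float = 8.0
    cycling_amplitude: float = 2.0
    cycling_noise_sd: float = 1.0
    n_timepoints: int = 24
    sampling_interval_h: float = 2.0
    period_h: float = 24.0
    tissues: tuple[str, ...] = ("liver", "pituitary", "nih3t3")

    # RNAi screen: two pools per gene
    disturbance_shift_sd: float = 2.5
    screen_noise_sd: float = 1.0

    # genetic-interaction network
    p_edge_clock_clock: float = 0.4
    p_edge_background: float = 0.01

    # tissue ubiquity (Poisson counts) and fly homology (Bernoulli)
    ubiquity_mean_clock: float = 20.0
    ubiquity_mean_nonclock: float = 3.0
    homology_p_clock: float = 0.5
    homology_p_nonclock: float = 0.25

    # per-feature i.i.d. Bernoulli missingness, independent of class
    missing_rate_cycling: float = 0.05
    missing_rate_screen: float = 0.05
    missing_rate_ubiquity: float = 0.05
    missing_rate_homology: float = 0.05

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not 0 < self.n_clock < self.n_genes:
            raise ValueError("need 0 < n_clock < n_genes")
        if self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")
        if self.cycling_noise_sd <= 0 or self.screen_noise_sd <= 0:
            raise ValueError("noise SDs must be strictly positive")
        if self.cycling_amplitude < 0 or self.disturbance_shift_sd < 0:
            raise ValueError("effect sizes must be nonnegative")
        if self.n_timepoints < 8:
            raise ValueError("need at least 8 time points")
        for name in (
            "p_edge_clock_clock",
            "p_edge_background",
            "homology_p_clock",
            "homology_p_nonclock",
            "missing_rate_cycling",
            "missing_rate_screen",
            "missing_rate_ubiquity",
            "missing_rate_homology",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.ubiquity_mean_clock < 0 or self.ubiquity_mean_nonclock < 0:
            raise ValueError("ubiquity Poisson means must be nonnegative")

    @property
    def times_h(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.sampling_interval_h

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tissues"] = list(self.tissues)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "tissues" in d:
            d["tissues"] = tuple(d["tissues"])
        return cls(**d)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def gene_ids(config: SimulationConfig) -> list[str]:
    width = max(5, len(str(config.n_genes - 1)))
    return [f"g{i:0{width}d}" for i in range(config.n_genes)]


def clock_gene_ids(config: SimulationConfig) -> list[str]:
    """Planted positive class, placed at random positions in the universe."""
    ids = gene_ids(config)
    rng = _rng(config, _STREAM_LABELS)
    idx = rng.choice(config.n_genes, size=config.n_clock, replace=False)
    return sorted(ids[i] for i in idx)


def truth_labels(config: SimulationConfig) -> pd.DataFrame:
    clock = set(clock_gene_ids(config))
    ids = gene_ids(config)
    return pd.DataFrame(
        {
            "gene_id": ids,
            "label": [CLOCK_LABEL if g in clock else NONCLOCK_LABEL for g in ids],
        }
    )


def _missing_mask(rng: np.random.Generator, n: int, rate: float) -> np.ndarray:
    """True where the gene's value for this feature is observed."""
    return rng.random(n) >= rate


def simulate_time_courses(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Per-tissue expression matrices (genes x times, hour-labelled columns).

    Clock genes follow a cosine at ``period_h`` with a uniform random phase
    per gene and tissue plus i.i.d. Gaussian noise; nonclock genes are noise
    around a constant baseline.  Genes masked missing for the cycling feature
    are dropped from every tissue.
    """
    rng = _rng(config, _STREAM_TIMECOURSE)
    ids = np.array(gene_ids(config))
    clock = np.isin(ids, clock_gene_ids(config))
    t = config.times_h
    keep = _missing_mask(rng, config.n_genes, config.missing_rate_cycling)

    out: dict[str, pd.DataFrame] = {}
    for tissue in config.tissues:
        phases = rng.uniform(0.0, config.period_h, size=config.n_genes)
        signal = config.cycling_amplitude * np.cos(
            2.0 * np.pi * (t[None, :] - phases[:, None]) / config.period_h
        )
        signal[~clock, :] = 0.0
        noise = rng.normal(0.0, config.cycling_noise_sd, size=(config.n_genes, t.size))
        values = config.baseline_expression + signal + noise
        df = pd.DataFrame(values, index=ids, columns=[f"{h:g}" for h in t])
        df.index.name = "gene_id"
        out[tissue] = df.loc[keep]
    return out


def cycling_pvalue_table(
    time_courses: Mapping[str, pd.DataFrame],
    times_h: np.ndarray,
    period_h: float = 24.0,
) -> pd.DataFrame:
    """Apply the cosinor stand-in to each tissue, one p-value column per tissue."""
    cols = {}
    index = None
    for tissue, df in time_courses.items():
        p = cosinor_pvalues(df.to_numpy(dtype=float), times_h, period_h)
        cols[f"p_{tissue}"] = pd.Series(p, index=df.index)
        index = df.index if index is None else index.union(df.index)
    out = pd.DataFrame(cols, index=index)
    out.index.name = "gene_id"
    return out.reset_index()


def simulate_screen_logratios(config: SimulationConfig) -> pd.DataFrame:
    """RNAi-screen table: two pools per gene, period and amplitude log-ratios.

    Clock-gene knockdowns shift both pools' log-ratios by
    ``disturbance_shift_sd`` noise-SD units with a random sign per gene and
    parameter (knockdowns may lengthen or shorten the period and raise or
    damp the amplitude); nonclock genes are centred at zero.
    """
    rng = _rng(config, _STREAM_SCREEN)
    ids = np.array(gene_ids(config))
    clock = np.isin(ids, clock_gene_ids(config))
    n = config.n_genes
    shift = config.disturbance_shift_sd * config.screen_noise_sd

    sign_p = rng.choice([-1.0, 1.0], size=n)
    sign_a = rng.choice([-1.0, 1.0], size=n)
    mu_p = np.where(clock, sign_p * shift, 0.0)
    mu_a = np.where(clock, sign_a * shift, 0.0)

    keep = _missing_mask(rng, n, config.missing_rate_screen)
    frames = []
    for pool in (1, 2):
        lp = mu_p + rng.normal(0.0, config.screen_noise_sd, size=n)
        la = mu_a + rng.normal(0.0, config.screen_noise_sd, size=n)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": ids,
                    "pool": pool,
                    "log_period_ratio": lp,
                    "log_amp_ratio": la,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out = out[out["gene_id"].isin(ids[keep])].reset_index(drop=True)
    return out.sort_values(["gene_id", "pool"], kind="mergesort").reset_index(drop=True)


def simulate_interaction_network(
    config: SimulationConfig, self_loop_genes: Sequence[str] = ()
) -> pd.DataFrame:
    """Undirected Bernoulli edge list over the gene universe.

    Clock-clock pairs use ``p_edge_clock_clock``; every other pair uses
    ``p_edge_background``.  No self-loops are emitted unless explicitly
    injected through ``self_loop_genes`` (provided so the downstream nonself
    counting rule can be exercised).
    """
    rng = _rng(config, _STREAM_NETWORK)
    ids = np.array(gene_ids(config))
    clock = np.isin(ids, clock_gene_ids(config))

    iu, ju = np.triu_indices(config.n_genes, k=1)
    both_clock = clock[iu] & clock[ju]
    p = np.where(both_clock, config.p_edge_clock_clock, config.p_edge_background)
    mask = rng.random(iu.size) < p

    edges = pd.DataFrame({"gene_a": ids[iu[mask]], "gene_b": ids[ju[mask]]})
    if self_loop_genes:
        loops = pd.DataFrame({"gene_a": list(self_loop_genes), "gene_b": list(self_loop_genes)})
        edges = pd.concat([edges, loops], ignore_index=True)
    return edges.reset_index(drop=True)


def simulate_ubiquity(config: SimulationConfig) -> pd.DataFrame:
    """Per-gene tissue counts: class-specific Poisson draws."""
    rng = _rng(config, _STREAM_UBIQUITY)
    ids = np.array(gene_ids(config))
    clock = np.isin(ids, clock_gene_ids(config))
    mean = np.where(clock, config.ubiquity_mean_clock, config.ubiquity_mean_nonclock)
    counts = rng.poisson(mean)
    keep = _missing_mask(rng, config.n_genes, config.missing_rate_ubiquity)
    return pd.DataFrame({"gene_id": ids[keep], "n_tissues": counts[keep]}).reset_index(
        drop=True
    )


def simulate_homology(config: SimulationConfig) -> pd.DataFrame:
    """Per-gene Boolean fly-homology flag, Bernoulli per class."""
    rng = _rng(config, _STREAM_HOMOLOGY)
    ids = np.array(gene_ids(config))
    clock = np.isin(ids, clock_gene_ids(config))
    p = np.where(clock, config.homology_p_clock, config.homology_p_nonclock)
    flags = rng.random(config.n_genes) < p
    keep = _missing_mask(rng, config.n_genes, config.missing_rate_homology)
    return pd.DataFrame(
        {"gene_id": ids[keep], "has_fly_homolog": flags[keep].astype(int)}
    ).reset_index(drop=True)


def simulate_ubiquity_and_homology(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    return simulate_ubiquity(config), simulate_homology(config)


@dataclass
class SimulatedData:
    """Bundle of all raw synthetic inputs for one universe."""

    config: SimulationConfig
    truth: pd.DataFrame
    exemplars: list[str]
    time_courses: dict[str, pd.DataFrame] = field(repr=False)
    screen: pd.DataFrame = field(repr=False)
    network: pd.DataFrame = field(repr=False)
    ubiquity: pd.DataFrame = field(repr=False)
    homology: pd.DataFrame = field(repr=False)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.truth["gene_id"])


def simulate_all(config: SimulationConfig) -> SimulatedData:
    """Run every generator; the planted clock genes double as the exemplar set."""
    return SimulatedData(
        config=config,
        truth=truth_labels(config),
        exemplars=clock_gene_ids(config),
        time_courses=simulate_time_courses(config),
        screen=simulate_screen_logratios(config),
        network=simulate_interaction_network(config),
        ubiquity=simulate_ubiquity(config),
        homology=simulate_homology(config),
    )
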