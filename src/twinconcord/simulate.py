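"""Synthetic twin-embryo study generator.

Emulates the statistical structure the downstream analyses assume, so
that the whole pipeline is testable without any data download:

* MZ twin blastocyst pairs with a latent two-class structure
  (concordant / discordant cell allocation), each blastocyst holding
  roughly half the cells of an intact embryo, and discordance injected
  into the epiblast (EPI) compartment;
* DZ background pairs formed from independent intact-embryo draws;
* pair-correlated transcriptomes with a low-variance housekeeping
  panel, EPI-program genes that diverge only in discordant pairs, and
  an Xist-driven sex signal;
* blastomere-progeny EPI contributions drawn from a balanced/skewed
  mixture;
* paired developmental outcomes with a configurable co-blastocyst
  rate.

Each dataset component draws from its own RNG stream derived from the
master seed, so components are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .concordance import LineageCounts, TwinPairRecord
from .expression import HOUSEKEEPING_PANEL, PairedExpressionMatrix
from .tracing import TracedBlastocyst

__all__ = [
    "SkewMixture",
    "GeneratorConfig",
    "SimulatedStudy",
    "simulate_lineage_pairs",
    "simulate_expression_pairs",
    "simulate_tracing",
    "simulate_outcomes",
    "simulate_study",
]

#: EPI-program genes given real symbols first (germ-cell/pluripotency
#: program expressed in the epiblast).
EPI_PROGRAM_SYMBOLS = ("Nanog", "Bmp4", "Bmp8b", "Dazl", "Prdm14")

ARREST_STAGES = ("one-cell", "two-cell", "four-cell", "eight-cell", "morula")

_STREAMS = ("labels", "lineage", "expression", "tracing", "outcomes")


@dataclass(frozen=True)
class SkewMixture:
    """Two-component mixture of blastomere EPI-contribution patterns.

    The dominant fraction f in [0.5, 1] is drawn as 0.5 + 0.5*Beta(a,b)
    for the balanced component (mass near 0.5) and 1 - 0.5*Beta(a,b)
    for the skewed component (mass near 1).
    """

    w_balanced: float = 0.35
    w_skewed: float = 0.65
    balanced_beta: tuple[float, float] = (1.0, 6.0)
    skewed_beta: tuple[float, float] = (1.0, 3.0)

    def __post_init__(self) -> None:
        if abs(self.w_balanced + self.w_skewed - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if min(self.w_balanced, self.w_skewed) < 0:
            raise ValueError("mixture weights must be non-negative")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic twin-embryo study.

    Cell-count moments and rates default to the study conditions being
    emulated: MZ blastocysts of 32.1 +/- 15.0 total cells vs intact
    embryos of 70.8 +/- 13.6; a 64% latent-discordant class; 26,597
    detected protein-coding transcripts; and a 92% co-blastocyst rate.
    The TE/EPI/pEnd expected shares are an assumption (the emulated
    study reports no MZ lineage-fraction means); (0.60, 0.25, 0.15) is
    a plausible allocation for an expanded mouse blastocyst.
    """

    seed: int = 0
    # --- cohort sizes ---
    n_mz_pairs: int = 8
    n_dz_pairs: int = 38
    n_controls: int = 8
    # --- lineage counts ---
    p_discordant: float = 0.64
    mz_total_cells_mean: float = 32.1
    mz_total_cells_sd: float = 15.0
    intact_total_cells_mean: float = 70.8
    intact_total_cells_sd: float = 13.6
    lineage_fractions: tuple[float, float, float] = (0.60, 0.25, 0.15)
    #: within-pair count jitter SD per lineage (TE, EPI, pEnd); models the
    #: residual allocation noise between members of the same zygote
    count_jitter_sd: tuple[float, float, float] = (2.5, 0.7, 0.7)
    #: multiplicative EPI shrinkage applied to one member of discordant
    #: pairs (values >= 1 disable it); the reduction is floored at 3
    #: cells so that the EPI difference exceeds the background threshold
    #: with high probability
    epi_divergence_factor: float = 0.2
    te_divergence_factor: float = 1.0
    pend_divergence_factor: float = 1.0
    # --- expression ---
    n_genes: int = 26597
    n_housekeeping: int = 7
    n_epi_program: int = 50
    pair_corr: float = 0.9
    noise_sd: float = 1.0  # per-sample log2 SD of the stochastic part
    hk_noise_factor: float = 0.1
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    epi_divergence_log2: float = 1.5  # mean log2 downshift in one member
    epi_divergence_log2_sd: float = 0.5
    p_female: float = 0.25
    xist_male_log2: float = 3.0
    xist_female_log2: float = 9.0
    # --- tracing ---
    n_tracing: int = 36
    tracing_epi_mean: float = 15.0
    tracing_epi_sd: float = 5.0
    skew_mixture: SkewMixture = field(default_factory=SkewMixture)
    # --- outcomes ---
    n_outcome_pairs: int | None = None  # defaults to n_mz_pairs
    p_blastocyst: float = 0.85
    co_blastocyst_rate: float = 0.92
    arrest_probs: tuple[float, ...] = (0.05, 0.35, 0.25, 0.15, 0.20)

    def __post_init__(self) -> None:
        if isinstance(self.skew_mixture, dict):
            self.skew_mixture = SkewMixture(**self.skew_mixture)
        for name in ("n_mz_pairs", "n_dz_pairs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_controls < 0 or self.n_tracing < 0:
            raise ValueError("cohort sizes must be non-negative")
        for name in (
            "mz_total_cells_sd",
            "intact_total_cells_sd",
            "noise_sd",
            "tracing_epi_sd",
            "epi_divergence_log2_sd",
            "baseline_log2_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_discordant", "pair_corr", "p_female", "p_blastocyst", "co_blastocyst_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        fr = np.asarray(self.lineage_fractions, dtype=float)
        if fr.size != 3 or (fr < 0).any() or abs(fr.sum() - 1.0) > 1e-6:
            raise ValueError("lineage_fractions must be a non-negative triple summing to 1")
        if self.n_housekeeping + self.n_epi_program + 1 > self.n_genes:
            raise ValueError(
                "n_genes must be at least n_housekeeping + n_epi_program + 1 (one slot for Xist)"
            )
        ap = np.asarray(self.arrest_probs, dtype=float)
        if ap.size != len(ARREST_STAGES) or (ap < 0).any() or abs(ap.sum() - 1.0) > 1e-6:
            raise ValueError("arrest_probs must be a simplex over the five pre-blastocyst stages")
        # exchangeable pair-outcome construction needs a valid "neither" mass
        p, r = self.p_blastocyst, self.co_blastocyst_rate
        if 1.0 - 2.0 * p + p * r < -1e-12:
            raise ValueError("p_blastocyst/co_blastocyst_rate imply a negative 'neither' probability")

    def rng(self, stream: str) -> np.random.Generator:
        """Per-component generator derived from the master seed."""
        idx = _STREAMS.index(stream)
        return np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=(idx,)))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["skew_mixture"] = asdict(self.skew_mixture)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("lineage_fractions", "count_jitter_sd", "arrest_probs"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "skew_mixture" in d and isinstance(d["skew_mixture"], dict):
            sm = dict(d["skew_mixture"])
            for key in ("balanced_beta", "skewed_beta"):
                if key in sm:
                    sm[key] = tuple(sm[key])
            d["skew_mixture"] = SkewMixture(**sm)
        return cls(**d)


@dataclass
class SimulatedStudy:
    """Full synthetic study: lineage pairs, transcriptomes, tracing, outcomes."""

    config: GeneratorConfig
    lineage_pairs: list[TwinPairRecord]
    truth_labels: dict[str, str]
    expression: PairedExpressionMatrix
    tracing: list[TracedBlastocyst]
    outcomes: pd.DataFrame


def _truncated_normal_totals(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Integer totals from a normal truncated at zero (minimum 1 cell)."""
    if sd == 0:
        draws = np.full(size, mean)
    else:
        a = (0.0 - mean) / sd
        draws = sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)
    return np.maximum(1, np.rint(draws).astype(int))


def _draw_labels(config: GeneratorConfig) -> dict[str, str]:
    """Latent concordant/discordant labels for the MZ pairs.

    Drawn from a dedicated stream so lineage and expression simulation
    agree on the labels without passing state.
    """
    rng = config.rng("labels")
    draws = rng.random(config.n_mz_pairs) < config.p_discordant
    return {
        f"MZ{i + 1:03d}": ("discordant" if d else "concordant") for i, d in enumerate(draws)
    }


def _mz_pair_ids(config: GeneratorConfig) -> list[str]:
    return [f"MZ{i + 1:03d}" for i in range(config.n_mz_pairs)]


def _shrink(count: int, factor: float, rng: np.random.Generator, floor: int = 3) -> int:
    """Divergence shrinkage: at least ``floor`` cells removed (down to 0)."""
    target = int(np.rint(factor * count))
    return max(0, min(target, count - floor))


def simulate_lineage_pairs(
    config: GeneratorConfig,
) -> tuple[list[TwinPairRecord], dict[str, str]]:
    """MZ and DZ pairs of per-lineage cell counts plus latent MZ labels.

    Member A of an MZ pair draws its total from the truncated-at-zero
    MZ normal and splits it by a multinomial on the lineage fractions;
    member B repeats member A's counts with small per-lineage integer
    jitter (the shared-zygote model).  In latent-discordant pairs one
    member's EPI count is shrunk by ``epi_divergence_factor`` with the
    reduction floored at 3 cells, so the EPI difference exceeds the
    2-cell background threshold with probability > 0.9.  DZ pairs are
    random pairings of independent intact-embryo draws.
    """
    rng = config.rng("lineage")
    truth = _draw_labels(config)
    fractions = np.asarray(config.lineage_fractions, dtype=float)
    jitter = np.asarray(config.count_jitter_sd, dtype=float)
    pairs: list[TwinPairRecord] = []

    totals_a = _truncated_normal_totals(
        rng, config.mz_total_cells_mean, config.mz_total_cells_sd, config.n_mz_pairs
    )
    for pid, total_a in zip(_mz_pair_ids(config), totals_a):
        counts_a = rng.multinomial(total_a, fractions)
        noise = np.rint(rng.normal(0.0, 1.0, size=3) * jitter).astype(int)
        counts_b = np.maximum(0, counts_a + noise)
        if truth[pid] == "discordant":
            reduced_is_b = rng.random() < 0.5
            target = counts_b if reduced_is_b else counts_a
            target = target.copy()
            if config.epi_divergence_factor < 1.0:
                target[1] = _shrink(int(target[1]), config.epi_divergence_factor, rng)
            if config.te_divergence_factor < 1.0:
                target[0] = int(np.rint(config.te_divergence_factor * target[0]))
            if config.pend_divergence_factor < 1.0:
                target[2] = int(np.rint(config.pend_divergence_factor * target[2]))
            if reduced_is_b:
                counts_b = target
            else:
                counts_a = target
        pairs.append(
            TwinPairRecord(
                pair_id=pid,
                zygosity="MZ",
                member_a=LineageCounts(*[int(v) for v in counts_a]),
                member_b=LineageCounts(*[int(v) for v in counts_b]),
            )
        )

    dz_totals = _truncated_normal_totals(
        rng, config.intact_total_cells_mean, config.intact_total_cells_sd, 2 * config.n_dz_pairs
    )
    for i in range(config.n_dz_pairs):
        counts = [rng.multinomial(t, fractions) for t in dz_totals[2 * i : 2 * i + 2]]
        pairs.append(
            TwinPairRecord(
                pair_id=f"DZ{i + 1:03d}",
                zygosity="DZ",
                member_a=LineageCounts(*[int(v) for v in counts[0]]),
                member_b=LineageCounts(*[int(v) for v in counts[1]]),
            )
        )
    return pairs, truth


def _gene_names(config: GeneratorConfig) -> tuple[list[str], np.ndarray, np.ndarray, int]:
    """Gene symbols plus boolean masks (housekeeping, EPI-program) and Xist row."""
    n_hk, n_epi = config.n_housekeeping, config.n_epi_program
    hk = [HOUSEKEEPING_PANEL[i] if i < len(HOUSEKEEPING_PANEL) else f"Hk{i + 1}" for i in range(n_hk)]
    epi = [
        EPI_PROGRAM_SYMBOLS[i] if i < len(EPI_PROGRAM_SYMBOLS) else f"EpiProg{i + 1}"
        for i in range(n_epi)
    ]
    n_other = config.n_genes - n_hk - n_epi
    other = ["Xist"] + [f"Gene{i + 1:05d}" for i in range(n_other - 1)]
    names = hk + epi + other
    hk_mask = np.zeros(config.n_genes, dtype=bool)
    hk_mask[:n_hk] = True
    epi_mask = np.zeros(config.n_genes, dtype=bool)
    epi_mask[n_hk : n_hk + n_epi] = True
    return names, hk_mask, epi_mask, n_hk + n_epi


def simulate_expression_pairs(
    config: GeneratorConfig, truth: dict[str, str] | None = None
) -> PairedExpressionMatrix:
    """Pair-correlated linear-scale expression for twins and controls.

    Log2 expression of gene g in sample s is
    ``mu_g + s_g * (sqrt(rho) u_{g,pair} + sqrt(1-rho) v_{g,s}) + sex/divergence terms``
    where ``rho = pair_corr`` and ``s_g = noise_sd`` (scaled down by
    ``hk_noise_factor`` for the housekeeping panel).  With
    ``noise_sd = 0`` and divergence off, members of a pair are
    identical and every pair ratio is exactly 1.  EPI-program genes
    receive an additional log2 downshift in one member of each
    latent-discordant pair.  Xist separates female pairs (high) from
    male (low).  Output is strictly positive (2**log2).
    """
    if truth is None:
        truth = _draw_labels(config)
    missing = [pid for pid in _mz_pair_ids(config) if pid not in truth]
    if missing:
        raise ValueError(f"truth labels missing for pairs: {missing}")
    rng = config.rng("expression")
    names, hk_mask, epi_mask, xist_row = _gene_names(config)
    G = config.n_genes
    rho = config.pair_corr

    mu = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=G)
    mu[xist_row] = config.xist_male_log2
    s_g = np.full(G, config.noise_sd)
    s_g[hk_mask] *= config.hk_noise_factor

    pair_ids = _mz_pair_ids(config)
    samples, columns, groups, pair_map = [], [], {}, {}
    xist_delta = config.xist_female_log2 - config.xist_male_log2

    for pid in pair_ids:
        u = rng.normal(size=G)  # shared pair effect
        female = rng.random() < config.p_female
        div_on_a = rng.random() < 0.5
        shifts = rng.normal(config.epi_divergence_log2, config.epi_divergence_log2_sd, size=G)
        for member in ("a", "b"):
            v = rng.normal(size=G)
            x = mu + s_g * (np.sqrt(rho) * u + np.sqrt(1.0 - rho) * v)
            if female:
                x[xist_row] += xist_delta
            if truth[pid] == "discordant" and ((member == "a") == div_on_a):
                x[epi_mask] -= shifts[epi_mask]
            sid = f"{pid}{member}"
            samples.append(sid)
            columns.append(x)
            groups[sid] = "MZ_twin"
            pair_map[sid] = pid

    for i in range(config.n_controls):
        w = rng.normal(size=G)
        female = rng.random() < config.p_female
        x = mu + s_g * w
        if female:
            x[xist_row] += xist_delta
        sid = f"CTRL{i + 1:03d}"
        samples.append(sid)
        columns.append(x)
        groups[sid] = "control"

    values = pd.DataFrame(
        np.power(2.0, np.column_stack(columns)), index=pd.Index(names, name="gene"), columns=samples
    )
    return PairedExpressionMatrix(
        values=values,
        pair_map=pd.Series(pair_map),
        group=pd.Series(groups),
        scale="linear",
    )


def simulate_tracing(config: GeneratorConfig) -> list[TracedBlastocyst]:
    """Labeled-embryo EPI contributions from the balanced/skewed mixture.

    Per embryo the total EPI count is drawn from a truncated normal,
    the dominant fraction from the two-component Beta mixture, and the
    green/red progeny counts are the rounded split (dominant side
    assigned at random).  Embryos whose EPI rounds to zero are excluded
    from the output.
    """
    rng = config.rng("tracing")
    mix = config.skew_mixture
    records: list[TracedBlastocyst] = []
    for i in range(config.n_tracing):
        total = int(
            _truncated_normal_totals(rng, config.tracing_epi_mean, config.tracing_epi_sd, 1)[0]
        )
        if total < 1:  # pragma: no cover - _truncated_normal_totals floors at 1
            continue
        if rng.random() < mix.w_balanced:
            frac = 0.5 + 0.5 * rng.beta(*mix.balanced_beta)
        else:
            frac = 1.0 - 0.5 * rng.beta(*mix.skewed_beta)
        big = int(np.rint(frac * total))
        big = max(big, total - big)  # keep the dominant side dominant after rounding
        small = total - big
        if rng.random() < 0.5:
            epi_a, epi_b = big, small
        else:
            epi_a, epi_b = small, big
        records.append(
            TracedBlastocyst(embryo_id=f"T{i + 1:03d}", epi_a=epi_a, epi_b=epi_b, cohort="intact")
        )
    return records


def simulate_outcomes(config: GeneratorConfig) -> pd.DataFrame:
    """Paired developmental outcomes (final stage per member).

    The pair outcome type is drawn exchangeably: both members reach
    blastocyst with probability p*r, exactly one with 2p(1-r) and
    neither with 1-2p+pr, where p is the marginal blastocyst rate and
    r the conditional co-blastocyst rate; which member succeeds in a
    one-blastocyst pair is uniform, so member labels are symmetric.
    Arrested members draw their stage from ``arrest_probs``.
    """
    rng = config.rng("outcomes")
    n = config.n_outcome_pairs if config.n_outcome_pairs is not None else config.n_mz_pairs
    p, r = config.p_blastocyst, config.co_blastocyst_rate
    probs = np.array([p * r, 2 * p * (1 - r), max(0.0, 1 - 2 * p + p * r)])
    probs = probs / probs.sum()
    rows = []
    for i in range(n):
        kind = rng.choice(3, p=probs)
        if kind == 0:
            stages = ["blastocyst", "blastocyst"]
        elif kind == 1:
            arrested = str(rng.choice(ARREST_STAGES, p=config.arrest_probs))
            stages = ["blastocyst", arrested]
            if rng.random() < 0.5:
                stages.reverse()
        else:
            stages = [str(rng.choice(ARREST_STAGES, p=config.arrest_probs)) for _ in range(2)]
        for member, stage in zip(("a", "b"), stages):
            rows.append({"pair_id": f"P{i + 1:04d}", "member": member, "stage": stage})
    return pd.DataFrame(rows)


def simulate_study(config: GeneratorConfig) -> SimulatedStudy:
    """Generate every component of the synthetic study from one seed."""
    pairs, truth = simulate_lineage_pairs(config)
    expression = simulate_expression_pairs(config, truth)
    tracing = simulate_tracing(config)
    outcomes = simulate_outcomes(config)
    return SimulatedStudy(
        config=config,
        lineage_pairs=pairs,
        truth_labels=truth,
        expression=expression,
        tracing=tracing,
        outcomes=outcomes,
    )
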