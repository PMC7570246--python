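"""Synthetic MSAP/TMD band matrices with dose-dependent demethylation.

The generator emulates the statistical structure the analysis assumes rather
than any sequence-level mechanism.  Every locus carries a latent methylation
state in {I, II, III, IV} (unmethylated, fully methylated, hemi-methylated,
absent in both digests):

* **Baseline.** Each locus draws a baseline state from the marker system's
  state distribution ``pi``; all samples share it, which creates the locus
  structure real matrices have.  Each sample then redraws its state from
  ``pi`` with probability ``epimutation_rate`` — independent per-sample
  noise that supplies within-group variance without shifting the marginal
  state distribution.

* **Treatment.** A sample exposed to gamma dose g (Gy) and inhibitor
  concentration c (uM) demethylates each locus with

      p_dem = 1 - exp(-(beta_gr * g + beta_dnmti * c) * s * lambda_l)

  where the synergy factor ``s >= 1`` applies only when both mutagens are
  present (exponential saturation keeps p_dem in [0, 1) and monotone in
  dose), and ``lambda_l`` is a per-locus susceptibility multiplier,
  Gamma-distributed with mean 1 and squared coefficient of variation
  ``locus_dispersion`` and shared across samples — susceptible loci respond
  in every treated plant, which is what gives treatment classes coherent
  among-group structure.  Demethylation moves fully methylated loci either
  to hemi-methylated (probability ``alpha``) or all the way to unmethylated
  (``1 - alpha``); hemi-methylated loci demethylate fully; and
  double-absent loci (dense methylation) partially demethylate to
  hemi-methylated with probability ``p_dem * alpha``.  Whether a
  demethylating locus stops at hemi is treated as a property of its genomic
  context, so that split is also drawn per locus.  A high ``alpha``
  (hemi-accumulating, repeat-like) regime raises the hemi rate under
  treatment, a low ``alpha`` regime lowers both full and hemi rates.

States map to paired digest calls via I=(1,1), II=(1,0), III=(0,1),
IV=(0,0).  A :class:`TruthRecord` keeps latent states and realised tallies
so scoring can be tested against exact truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .band_data import BandMatrix, SampleMeta
from .datasets import GROUP_DESIGN

__all__ = [
    "SimConfig",
    "TruthRecord",
    "simulate_band_matrix",
    "simulate_study",
    "expected_state_probs",
    "expected_rates",
    "recover_parameters",
]

# Baseline state proportions (I, II, III, IV) matching the reference study's
# control groups: MSAP (221, 70, 102, 142)/535, TMD (97, 53, 16, 61)/227.
DEFAULT_PI = {
    "MSAP": (221 / 535, 70 / 535, 102 / 535, 142 / 535),
    "TMD": (97 / 227, 53 / 227, 16 / 227, 61 / 227),
}
# Hemi-split: MSAP loci mostly demethylate fully (alpha low); TMD samples
# repeat-rich, densely methylated regions that shed one strand first.
DEFAULT_ALPHA = {"MSAP": 0.3, "TMD": 0.8}

STATE_TO_CALLS = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.int8)


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults reproduce the reference study design."""

    n_loci: dict[str, int] = field(
        default_factory=lambda: {"MSAP": 102, "TMD": 60}
    )
    design: tuple = GROUP_DESIGN  # (group, n, gamma Gy, agent, conc uM)
    pi: dict[str, tuple] = field(default_factory=lambda: dict(DEFAULT_PI))
    alpha: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ALPHA))
    beta_gr: float = 2.0e-4  # demethylation rate per Gy
    beta_dnmti: float = 1.9e-3  # demethylation rate per uM
    synergy: float = 1.3  # multiplicative rate factor when both present
    epimutation_rate: float = 0.003  # per-sample baseline redraw probability
    locus_dispersion: float = 15.0  # squared CV of per-locus susceptibility
    seed: int = 0

    def __post_init__(self) -> None:
        for sys_, pi in self.pi.items():
            if len(pi) != 4 or any(p < 0 for p in pi) or abs(sum(pi) - 1) > 1e-9:
                raise ValueError(f"pi for {sys_!r} must be 4 non-negative probs summing to 1")
        for a in self.alpha.values():
            if not 0 <= a <= 1:
                raise ValueError("alpha must lie in [0, 1]")
        if self.beta_gr < 0 or self.beta_dnmti < 0:
            raise ValueError("dose-response coefficients must be >= 0")
        if self.synergy < 1:
            raise ValueError("synergy factor must be >= 1")
        if not 0 <= self.epimutation_rate <= 1:
            raise ValueError("epimutation_rate must lie in [0, 1]")
        if self.locus_dispersion < 0:
            raise ValueError("locus_dispersion must be >= 0")


@dataclass
class TruthRecord:
    """Latent states and realised tallies behind one simulated matrix."""

    marker_system: str
    sample_ids: list[str]
    locus_ids: list[str]
    states_before: np.ndarray  # samples x loci, int8 codes 0..3 = I..IV
    states_after: np.ndarray
    group_of_sample: list[str]

    def group_tallies(self) -> dict[str, np.ndarray]:
        """Realised state counts (I..IV) per group after treatment."""
        out: dict[str, np.ndarray] = {}
        for g in dict.fromkeys(self.group_of_sample):
            rows = [i for i, lab in enumerate(self.group_of_sample) if lab == g]
            out[g] = np.bincount(self.states_after[rows].ravel(), minlength=4)
        return out


def _dose_rate(config: SimConfig, gamma_dose: float, dnmti_conc: float) -> float:
    rate = config.beta_gr * gamma_dose + config.beta_dnmti * dnmti_conc
    if gamma_dose > 0 and dnmti_conc > 0:
        rate *= config.synergy
    return rate


def demethylation_prob(config: SimConfig, gamma_dose: float, dnmti_conc: float) -> float:
    """Marginal per-locus demethylation probability for one exposure.

    Per-locus susceptibility multipliers are Gamma(1/d, d)-distributed
    (mean 1, squared CV ``locus_dispersion`` = d), so the marginal is
    1 - (1 + rate * d)^(-1/d), which reduces to 1 - exp(-rate) at d = 0.
    """
    rate = _dose_rate(config, gamma_dose, dnmti_conc)
    d = config.locus_dispersion
    if d == 0:
        return 1.0 - np.exp(-rate)
    return 1.0 - (1.0 + rate * d) ** (-1.0 / d)


def expected_state_probs(config: SimConfig, marker_system: str,
                         gamma_dose: float, dnmti_conc: float) -> np.ndarray:
    """Analytic post-treatment state distribution for one exposure."""
    pi = np.asarray(config.pi[marker_system], dtype=float)
    a = config.alpha[marker_system]
    p = demethylation_prob(config, gamma_dose, dnmti_conc)
    return np.array(
        [
            pi[0] + pi[1] * p * (1 - a) + pi[2] * p,
            pi[1] * (1 - p),
            pi[2] * (1 - p) + (pi[1] + pi[3]) * p * a,
            pi[3] * (1 - p * a),
        ]
    )


def expected_rates(config: SimConfig, marker_system: str,
                   gamma_dose: float, dnmti_conc: float) -> dict[str, float]:
    """Analytic total/full/hemi/non methylation percentages for one exposure."""
    q = expected_state_probs(config, marker_system, gamma_dose, dnmti_conc)
    return {
        "total": 100.0 * (1.0 - q[0]),
        "full": 100.0 * q[1],
        "hemi": 100.0 * q[2],
        "non": 100.0 * q[0],
    }


def _draw_states(rng: np.random.Generator, pi: np.ndarray, size) -> np.ndarray:
    cum = np.cumsum(pi)
    cum[-1] = 1.0
    return np.searchsorted(cum, rng.random(size), side="right").astype(np.int8)


def _samples_from_design(design) -> list[SampleMeta]:
    samples = []
    for group, n, dose, agent, conc in design:
        for i in range(1, n + 1):
            samples.append(
                SampleMeta(
                    sample_id=f"{group}_{i:02d}",
                    treatment_group=group,
                    gamma_dose=dose,
                    dnmti_agent=agent,
                    dnmti_conc=conc,
                )
            )
    return samples


def simulate_band_matrix(
    config: SimConfig,
    marker_system: str = "MSAP",
    rng: np.random.Generator | None = None,
) -> tuple[BandMatrix, TruthRecord]:
    """Draw one band matrix plus its truth record.

    Deterministic given (config.seed, marker_system) when ``rng`` is not
    supplied; marker systems draw from independent streams so MSAP and TMD
    baselines are uncorrelated, mirroring the weak cross-system correlation
    such designs show.
    """
    if marker_system not in config.n_loci:
        raise ValueError(f"no locus count configured for {marker_system!r}")
    if rng is None:
        # stable stream per marker system (process-independent, unlike hash())
        stream = zlib.crc32(marker_system.encode()) % (2**31)
        rng = np.random.default_rng([config.seed, stream])
    samples = _samples_from_design(config.design)
    if not samples:
        raise ValueError("design has zero samples")
    n, m = len(samples), config.n_loci[marker_system]
    pi = np.asarray(config.pi[marker_system], dtype=float)
    a = config.alpha[marker_system]

    baseline = _draw_states(rng, pi, m)
    states = np.tile(baseline, (n, 1))
    noise = rng.random((n, m)) < config.epimutation_rate
    states[noise] = _draw_states(rng, pi, int(noise.sum()))
    before = states.copy()

    disp = config.locus_dispersion
    if disp > 0:  # locus-shared susceptibility: treated samples hit the same loci
        lam = rng.gamma(shape=1.0 / disp, scale=disp, size=m)[None, :]
    else:
        lam = np.ones((1, m))
    rates = np.array([_dose_rate(config, s.gamma_dose, s.dnmti_conc)
                      for s in samples])[:, None]
    pdem = 1.0 - np.exp(-rates * lam)
    u = rng.random((n, m))
    hit = u < pdem
    # where a demethylating locus stops (hemi vs fully demethylated) is a
    # property of its genomic context, so the split is drawn per locus
    split = np.broadcast_to(rng.random(m) < a, (n, m))
    out = states.copy()
    out[(states == 1) & hit & split] = 2  # full -> hemi
    out[(states == 1) & hit & ~split] = 0  # full -> unmethylated
    out[(states == 2) & hit] = 0  # hemi -> unmethylated
    out[(states == 3) & hit & split] = 2  # dense -> hemi

    locus_ids = [f"{marker_system}L{j + 1:03d}" for j in range(m)]
    calls = STATE_TO_CALLS[out]
    bm = BandMatrix(marker_system, locus_ids, samples, calls[:, :, 0], calls[:, :, 1])
    truth = TruthRecord(
        marker_system=marker_system,
        sample_ids=[s.sample_id for s in samples],
        locus_ids=locus_ids,
        states_before=before,
        states_after=out,
        group_of_sample=[s.treatment_group for s in samples],
    )
    return bm, truth


def simulate_study(config: SimConfig) -> dict[str, tuple[BandMatrix, TruthRecord]]:
    """Simulate every marker system in the config over one shared design."""
    return {
        sys_: simulate_band_matrix(config, sys_) for sys_ in sorted(config.n_loci)
    }


def recover_parameters(
    matrix: BandMatrix, truth: TruthRecord, config: SimConfig
) -> pd.DataFrame:
    """Compare scored group rates with the generator's analytic expectations.

    Returns one row per (group, rate) with observed and expected percentages,
    the sampling standard error and a ``within_3se`` flag.  Because samples
    share a per-locus baseline, the independent unit for group rates is the
    locus: SE = 100 * sqrt(q (1 - q) / n_loci).  Raises if the matrix and
    truth record disagree.
    """
    from .band_data import Grouping
    from .methylation import count_band_types, methylation_rates

    if matrix.sample_ids != truth.sample_ids or matrix.locus_ids != truth.locus_ids:
        raise ValueError("matrix and truth record do not match")
    if not np.array_equal(STATE_TO_CALLS[truth.states_after][:, :, 0], matrix.calls_m):
        raise ValueError("matrix calls disagree with truth states")

    grouping = Grouping.from_samples(matrix.samples, "treatment_group")
    counts = count_band_types(matrix, grouping)
    exposure = {s.treatment_group: (s.gamma_dose, s.dnmti_conc) for s in matrix.samples}
    n_loci = matrix.n_loci
    rows = []
    for c in counts:
        prof = methylation_rates(c)
        dose, conc = exposure[c.group]
        exp = expected_rates(config, matrix.marker_system, dose, conc)
        for rate in ("total", "full", "hemi", "non"):
            e = exp[rate]
            q = e / 100.0
            se = 100.0 * np.sqrt(q * (1 - q) / n_loci)
            obs = prof.rate(rate)
            rows.append(
                {
                    "group": c.group,
                    "rate": rate,
                    "observed": obs,
                    "expected": e,
                    "se": se,
                    "z": (obs - e) / se if se > 0 else 0.0,
                    "within_3se": bool(abs(obs - e) <= 3 * se) if se > 0 else obs == e,
                }
            )
    return pd.DataFrame(rows)
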