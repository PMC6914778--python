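"""Generative model for two-color reporter measurements in intestine cells.

The simulator emulates the structure of in vivo dual-reporter image
cytometry in the *C. elegans* intestine: a handful of independent
experiments, ~10 animals each, eight measured cells spread over intestine
rings 1-4, and two fluorescence channels per cell.  Each cell's intensity in
a channel is a product of median-1 lognormal factors

    intensity = background + setpoint(promoter, ring)
                * G_animal * G_cell * P(promoter) * gamma(allele) * eps(channel)

where ``G_animal`` is shared by every cell of an animal, ``G_cell`` by both
channels of a cell (general protein expression capacity), ``P`` is drawn
once per distinct promoter per cell (pathway activation), ``gamma`` once per
reporter copy (allele-intrinsic noise) and ``eps`` is per-channel
multiplicative measurement noise.  In a Type I pair both channels carry the
same promoter and share the ``P`` draw; in a Type II pair the promoters and
their ``P`` draws are distinct.

Because every factor is lognormal with median 1, the variance bins the
decomposition recovers have exact closed forms (see :func:`expected_eta2`),
which the test-suite uses as an oracle for parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

CHANNEL_A = "ch_green"
CHANNEL_B = "ch_red"
CHANNELS = (CHANNEL_A, CHANNEL_B)
RINGS = (1, 2, 3, 4)

#: default ring-specific expression setpoints (arbitrary intensity units).
#: Ratios between promoters differ by ring, encoding the rigid cell-fate
#: specific ratiometric setpoint the decomposition has to normalise away.
DEFAULT_SETPOINTS: Dict[Tuple[str, int], float] = {
    ("hsp-16.2", 1): 150.0, ("hsp-16.2", 2): 120.0,
    ("hsp-16.2", 3): 180.0, ("hsp-16.2", 4): 100.0,
    ("vit-2", 1): 60.0, ("vit-2", 2): 90.0,
    ("vit-2", 3): 45.0, ("vit-2", 4): 75.0,
    ("eft-3", 1): 200.0, ("eft-3", 2): 160.0,
    ("eft-3", 3): 240.0, ("eft-3", 4): 130.0,
}

LATENT_COLUMNS = (
    "latent_G_animal", "latent_G_cell",
    "latent_P_" + CHANNEL_A, "latent_P_" + CHANNEL_B,
    "latent_gamma_" + CHANNEL_A, "latent_gamma_" + CHANNEL_B,
    "latent_eps_" + CHANNEL_A, "latent_eps_" + CHANNEL_B,
)

TYPE_I = "typeI"
TYPE_II = "typeII"

SCENARIOS = ("paper_like", "yeast_like", "high_signaling", "null_no_variation")


@dataclass
class GenerativeParams:
    """Parameters of the lognormal product model.

    All ``sigma_*`` values are the scale parameters (log-space standard
    deviations) of median-1 lognormal factors; they are dimensionless.
    """

    promoter_a: str = "hsp-16.2"
    promoter_b: str = "vit-2"
    experiment_type: str = TYPE_II
    n_experiments: int = 3
    n_animals_per_experiment: int = 10
    cells_per_animal: int = 8
    sigma_G_animal: float = 0.25
    sigma_G_cell: float = 0.31
    sigma_P: float = 0.10
    sigma_gamma: float = 0.03
    sigma_meas: float = 0.03
    setpoints: Dict[Tuple[str, int], float] = field(
        default_factory=lambda: dict(DEFAULT_SETPOINTS))
    background: Dict[str, float] = field(
        default_factory=lambda: {CHANNEL_A: 0.0, CHANNEL_B: 0.0})
    dropout_p: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_G_animal", "sigma_G_cell", "sigma_P",
                     "sigma_gamma", "sigma_meas"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_experiments", "n_animals_per_experiment",
                     "cells_per_animal"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if any(v <= 0 for v in self.setpoints.values()):
            raise ValueError("all setpoints must be > 0")
        if any(v < 0 for v in self.background.values()):
            raise ValueError("background must be >= 0")
        if self.experiment_type not in (TYPE_I, TYPE_II):
            raise ValueError(
                f"experiment_type must be '{TYPE_I}' or '{TYPE_II}'")
        if self.experiment_type == TYPE_I and self.promoter_a != self.promoter_b:
            raise ValueError("Type I pairs must use a single promoter on "
                             "both channels")

    @property
    def channel_promoters(self) -> Dict[str, str]:
        return {CHANNEL_A: self.promoter_a, CHANNEL_B: self.promoter_b}

    def setpoint(self, promoter: str, ring: int) -> float:
        try:
            return self.setpoints[(promoter, ring)]
        except KeyError:
            raise KeyError(f"no setpoint for promoter {promoter!r} in ring "
                           f"{ring}") from None


@dataclass(frozen=True)
class ExpectedEta2:
    """Closed-form variance bins implied by a :class:`GenerativeParams`.

    Under the median-1 lognormal product model the decomposition's bins are
    exactly (``sG2 = sigma_G_animal**2 + sigma_G_cell**2``)::

        eta2_G_true     = e**sG2 - 1
        eta2_P_true     = e**sG2 * (e**sigma_P**2 - 1)
        eta2_gamma_true = e**(sG2 + sigma_P**2)
                          * (e**(sigma_gamma**2 + sigma_meas**2) - 1)

    and they sum to the per-channel CV^2.  Per-channel measurement noise is
    uncorrelated between channels, so it lands in the intrinsic bin, just as
    it would for real microscopy data.
    """

    eta2_gamma_true: float
    eta2_P_true: float
    eta2_G_true: float
    cv2_true: float
    correlated_type1_true: float


def expected_eta2(params: GenerativeParams) -> ExpectedEta2:
    """Evaluate the closed-form variance bins for ``params`` (background 0)."""
    sG2 = params.sigma_G_animal ** 2 + params.sigma_G_cell ** 2
    sP2 = params.sigma_P ** 2
    su2 = params.sigma_gamma ** 2 + params.sigma_meas ** 2
    eta2_G = math.expm1(sG2)
    eta2_P = math.exp(sG2) * math.expm1(sP2)
    eta2_gamma = math.exp(sG2 + sP2) * math.expm1(su2)
    return ExpectedEta2(
        eta2_gamma_true=eta2_gamma,
        eta2_P_true=eta2_P,
        eta2_G_true=eta2_G,
        cv2_true=math.expm1(sG2 + sP2 + su2),
        correlated_type1_true=math.expm1(sG2 + sP2),
    )


def default_params(scenario: str, **overrides) -> GenerativeParams:
    """Return generative parameters for a named scenario.

    ``paper_like``
        dominant shared expression capacity, small pathway and intrinsic
        factors: Type I allele-vs-allele R^2 above 0.9 and eta2_G more than
        an order of magnitude above eta2_gamma.
    ``yeast_like``
        intrinsic scale tripled (yeast-style allele noise).
    ``high_signaling``
        inflated pathway activation noise.
    ``null_no_variation``
        every sigma zero; intensities equal their setpoints exactly.
    """
    base = dict(sigma_G_animal=0.25, sigma_G_cell=0.31, sigma_P=0.10,
                sigma_gamma=0.03, sigma_meas=0.03)
    if scenario == "paper_like":
        pass
    elif scenario == "yeast_like":
        base["sigma_gamma"] = 0.09
    elif scenario == "high_signaling":
        base["sigma_P"] = 0.40
    elif scenario == "null_no_variation":
        base = dict.fromkeys(base, 0.0)
    else:
        raise ValueError(
            f"unknown scenario {scenario!r}; valid scenarios: "
            + ", ".join(SCENARIOS))
    base.update(overrides)
    return GenerativeParams(**base)


def type1_params(params: GenerativeParams, promoter: str | None = None,
                 **overrides) -> GenerativeParams:
    """Type I counterpart of ``params``: both channels on one promoter."""
    promoter = promoter or params.promoter_a
    return replace(params, promoter_a=promoter, promoter_b=promoter,
                   experiment_type=TYPE_I, **overrides)


def _cell_ring(cell_index: int) -> Tuple[int, int]:
    ring = RINGS[cell_index % len(RINGS)]
    position = cell_index // len(RINGS) + 1
    return ring, position


def simulate_cells(params: GenerativeParams,
                   include_latent: bool = True) -> pd.DataFrame:
    """Simulate one per-cell measurement table.

    Returns one row per measured cell with the canonical columns
    ``experiment_id, animal_id, ring, cell_id, nucleus_count`` followed by
    the two channel intensities and (optionally) the latent lognormal
    factors under ``latent_*`` columns for recovery tests.

    Randomness is counter-seeded: the animal-level factor uses a stream
    keyed on (seed, experiment, animal) and each cell's factors a stream
    keyed on (seed, experiment, animal, cell), so subsetting animals or
    cells leaves every other draw unchanged.
    """
    p = params
    same_promoter = p.experiment_type == TYPE_I
    records: list[dict] = []
    for e in range(p.n_experiments):
        exp_id = f"exp{e + 1}"
        for a in range(p.n_animals_per_experiment):
            animal_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=p.seed, spawn_key=(e, a)))
            g_animal = math.exp(p.sigma_G_animal * animal_rng.standard_normal())
            for c in range(p.cells_per_animal):
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=p.seed, spawn_key=(e, a, c)))
                g_cell = math.exp(p.sigma_G_cell * rng.standard_normal())
                p_a = math.exp(p.sigma_P * rng.standard_normal())
                p_b = p_a if same_promoter else math.exp(
                    p.sigma_P * rng.standard_normal())
                gam = rng.standard_normal(2)
                eps = rng.standard_normal(2)
                keep = p.dropout_p == 0.0 or rng.uniform() >= p.dropout_p
                if not keep:
                    continue
                ring, pos = _cell_ring(c)
                factors = {
                    CHANNEL_A: (p_a, math.exp(p.sigma_gamma * gam[0]),
                                math.exp(p.sigma_meas * eps[0])),
                    CHANNEL_B: (p_b, math.exp(p.sigma_gamma * gam[1]),
                                math.exp(p.sigma_meas * eps[1])),
                }
                row = {
                    "experiment_id": exp_id,
                    "animal_id": f"{exp_id}_a{a + 1:02d}",
                    "ring": ring,
                    "cell_id": f"int{ring}.{pos}",
                    "nucleus_count": 2,
                }
                for ch in CHANNELS:
                    pf, gf, ef = factors[ch]
                    setpoint = p.setpoint(p.channel_promoters[ch], ring)
                    row[ch] = (p.background[ch]
                               + setpoint * g_animal * g_cell * pf * gf * ef)
                if include_latent:
                    row["latent_G_animal"] = g_animal
                    row["latent_G_cell"] = g_cell
                    for ch in CHANNELS:
                        pf, gf, ef = factors[ch]
                        row["latent_P_" + ch] = pf
                        row["latent_gamma_" + ch] = gf
                        row["latent_eps_" + ch] = ef
                records.append(row)
    columns = ["experiment_id", "animal_id", "ring", "cell_id",
               "nucleus_count", *CHANNELS]
    if include_latent:
        columns += list(LATENT_COLUMNS)
    return pd.DataFrame.from_records(records, columns=columns)


def strip_latent(cells: pd.DataFrame) -> pd.DataFrame:
    """Drop the latent truth columns, producing a blind measurement table."""
    return cells.drop(columns=[c for c in LATENT_COLUMNS
                               if c in cells.columns])
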