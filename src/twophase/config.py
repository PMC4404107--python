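"""Scenario configuration: true model coefficients and population structure.

:class:`TrueModel` holds the log-odds coefficients of the patient-level
logistic model used to generate outcomes; :class:`PopulationConfig` describes
the registrant population (stratum sizes, clinic counts, covariate marginals,
between-cohort heterogeneity, RNG seed).  :func:`default_config` returns the
configuration that emulates the Malawi survey.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import survey

#: Slope names, in design-matrix order (intercept excluded).
SLOPE_NAMES = (
    "age_lin",
    "age_quad",
    "female",
    "who34",
    "south",
    "year_2006",
    "year_2007",
    "private",
    "private_2006",
    "private_2007",
)

#: Age bands for covariate generation: (low, high) inclusive, in years.
AGE_BANDS = ((16, 25), (26, 35), (36, 45), (46, 55), (56, 65), (66, 80))

REGISTRATION_YEARS = (2005, 2006, 2007)
CLINIC_TYPES = ("public", "private")


@dataclass
class TrueModel:
    """Log-odds coefficients of the outcome-generating logistic model.

    Age enters through the transform ``x = (age - 45) / 10`` with linear and
    quadratic terms, so the referent age is 45 years and ``beta_age_quadratic``
    is the log odds ratio per decade-squared away from 45.  ``intercept`` may
    be ``None``, in which case it is calibrated to a target marginal outcome
    rate before outcomes are drawn.
    """

    intercept: float | None = None
    beta_age_linear: float = 0.0
    beta_age_quadratic: float = 0.0
    beta_female: float = 0.0
    beta_who34: float = 0.0
    beta_south: float = 0.0
    beta_2006: float = 0.0
    beta_2007: float = 0.0
    beta_private: float = 0.0
    beta_private_2006: float = 0.0
    beta_private_2007: float = 0.0

    _FIELD_BY_TERM = {
        "age_lin": "beta_age_linear",
        "age_quad": "beta_age_quadratic",
        "female": "beta_female",
        "who34": "beta_who34",
        "south": "beta_south",
        "year_2006": "beta_2006",
        "year_2007": "beta_2007",
        "private": "beta_private",
        "private_2006": "beta_private_2006",
        "private_2007": "beta_private_2007",
    }

    def slopes(self) -> dict[str, float]:
        """Slopes keyed by design-matrix term name."""
        return {t: getattr(self, f) for t, f in self._FIELD_BY_TERM.items()}

    def coefficients(self) -> dict[str, float]:
        """All coefficients including the intercept; intercept must be set."""
        if self.intercept is None:
            raise ValueError("intercept is not set; calibrate it first")
        return {"intercept": self.intercept, **self.slopes()}

    def replace(self, **changes) -> "TrueModel":
        return dataclasses.replace(self, **changes)

    def validate(self) -> None:
        for term, value in self.slopes().items():
            if not math.isfinite(math.exp(value)):
                raise ValueError(f"slope {term!r} has non-finite odds ratio")

    @classmethod
    def from_odds_ratios(
        cls, odds_ratios: dict[str, float], intercept: float | None = None
    ) -> "TrueModel":
        """Build from ``{term: OR}`` (missing terms default to OR 1)."""
        kwargs = {
            cls._FIELD_BY_TERM[t]: math.log(orr) for t, orr in odds_ratios.items()
        }
        return cls(intercept=intercept, **kwargs)


@dataclass
class CovariateMarginals:
    """Marginal covariate distribution of the registrant population."""

    age_band_probs: tuple[float, ...]
    p_female: float
    p_who34: float
    p_south: float

    def validate(self) -> None:
        probs = (*self.age_band_probs, self.p_female, self.p_who34, self.p_south)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if len(self.age_band_probs) != len(AGE_BANDS):
            raise ValueError(f"expected {len(AGE_BANDS)} age-band probabilities")
        if abs(sum(self.age_band_probs) - 1.0) > 1e-12:
            raise ValueError("age-band probabilities must sum to 1")


@dataclass
class PopulationConfig:
    """Everything needed to generate a synthetic registrant population.

    ``stratum_sizes`` fixes the exact number of registrants in each
    (registration year, clinic type) cell.  ``cohort_heterogeneity`` gives
    Beta concentration parameters for the cohort-specific probabilities of
    being female / WHO stage 3-4: a cohort's probability is drawn from a Beta
    distribution with mean equal to the configured marginal and the given
    concentration, so finite values create realistic between-cohort variation
    in composition (``math.inf`` degenerates to the marginal exactly).
    """

    total_patients: int
    stratum_sizes: dict[tuple[int, str], int]
    covariate_marginals: CovariateMarginals
    coefficients: TrueModel
    n_clinics_public: int = 150
    n_clinics_private: int = 39
    quarters_per_year: int = 4
    cohort_heterogeneity: dict[str, float] = field(
        default_factory=lambda: {"female": 6.0, "who34": 6.0}
    )
    target_outcome_rate: float = survey.OVERALL_NEGATIVE_RATE
    seed: int = 20150407

    def validate(self) -> None:
        if sum(self.stratum_sizes.values()) != self.total_patients:
            raise ValueError(
                "stratum_sizes must sum to total_patients "
                f"({sum(self.stratum_sizes.values())} != {self.total_patients})"
            )
        if any(n < 0 for n in self.stratum_sizes.values()):
            raise ValueError("stratum sizes must be non-negative")
        for (year, ctype), n in self.stratum_sizes.items():
            if ctype not in CLINIC_TYPES:
                raise ValueError(f"unknown clinic type {ctype!r}")
            n_clinics = (
                self.n_clinics_public if ctype == "public" else self.n_clinics_private
            )
            if n > 0 and n_clinics == 0:
                raise ValueError(
                    f"stratum ({year}, {ctype}) has {n} patients but no clinics"
                )
        self.covariate_marginals.validate()
        self.coefficients.validate()
        for key, kappa in self.cohort_heterogeneity.items():
            if kappa <= 0:
                raise ValueError(f"concentration {key!r} must be positive")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted({y for y, _ in self.stratum_sizes}))

    def replace(self, **changes) -> "PopulationConfig":
        return dataclasses.replace(self, **changes)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stratum_sizes"] = {
            f"{year}/{ctype}": n for (year, ctype), n in self.stratum_sizes.items()
        }
        d["coefficients"] = dataclasses.asdict(self.coefficients)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationConfig":
        d = dict(d)
        sizes = {}
        for key, n in d["stratum_sizes"].items():
            year, ctype = key.split("/")
            sizes[(int(year), ctype)] = int(n)
        d["stratum_sizes"] = sizes
        d["covariate_marginals"] = CovariateMarginals(
            age_band_probs=tuple(d["covariate_marginals"]["age_band_probs"]),
            p_female=d["covariate_marginals"]["p_female"],
            p_who34=d["covariate_marginals"]["p_who34"],
            p_south=d["covariate_marginals"]["p_south"],
        )
        d["coefficients"] = TrueModel(**d["coefficients"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "PopulationConfig":
        """Load from YAML or JSON (by extension)."""
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))


def default_marginals() -> CovariateMarginals:
    n = survey.N_PATIENTS
    return CovariateMarginals(
        age_band_probs=tuple(
            c / n for c in survey.AGE_BAND_COUNTS.values()
        ),
        p_female=survey.PATIENT_MARGINALS["female"] / n,
        p_who34=survey.PATIENT_MARGINALS["who34"] / n,
        p_south=survey.PATIENT_MARGINALS["south"] / n,
    )


def default_true_model(intercept: float | None = None) -> TrueModel:
    """Gold-standard slopes (published adjusted ORs) on the log scale."""
    return TrueModel.from_odds_ratios(
        survey.GOLD_STANDARD_ODDS_RATIOS, intercept=intercept
    )


def default_config(seed: int = 20150407) -> PopulationConfig:
    """Configuration emulating the Malawi survey population."""
    # Fix the age-band probabilities so they sum to exactly 1 in floats.
    marg = default_marginals()
    probs = np.asarray(marg.age_band_probs, dtype=float)
    probs = probs / probs.sum()
    marg = CovariateMarginals(
        age_band_probs=tuple(float(p) for p in probs),
        p_female=marg.p_female,
        p_who34=marg.p_who34,
        p_south=marg.p_south,
    )
    cfg = PopulationConfig(
        total_patients=survey.N_PATIENTS,
        stratum_sizes=dict(survey.STRATUM_SIZES),
        covariate_marginals=marg,
        coefficients=default_true_model(),
        seed=seed,
    )
    cfg.validate()
    return cfg


def null_interaction_config(seed: int = 20150407) -> PopulationConfig:
    """Default configuration with the clinic-by-year interactions set to zero."""
    cfg = default_config(seed=seed)
    model = cfg.coefficients.replace(
        beta_private_2006=0.0, beta_private_2007=0.0, intercept=None
    )
    return cfg.replace(coefficients=model)


def scaled_config(factor: float, seed: int = 20150407) -> PopulationConfig:
    """Default configuration with stratum sizes scaled down by ``factor``.

    Useful for quick tests; cell sizes are rounded and kept >= 1, and clinic
    counts are scaled so cohort sizes stay realistic.
    """
    cfg = default_config(seed=seed)
    sizes = {k: max(1, round(v * factor)) for k, v in cfg.stratum_sizes.items()}
    return cfg.replace(
        total_patients=sum(sizes.values()),
        stratum_sizes=sizes,
        n_clinics_public=max(2, round(cfg.n_clinics_public * factor)),
        n_clinics_private=max(2, round(cfg.n_clinics_private * factor)),
    )
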