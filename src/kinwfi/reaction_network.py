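"""Chemical species, elementary steps and kinetic models.

A :class:`KineticModel` is a set of species plus mass-action elementary
steps whose rate constants follow the Arrhenius law.  Three built-in
models describe the benzylation of unprotected aniline (``1``) by benzyl
bromide (``BnBr``) to the mono- (``2``) and dibenzylated (``di-2``)
products:

* :func:`sn2_model` — two bimolecular substitution steps,
* :func:`sn1_model` — unimolecular ionization to a benzyl cation
  followed by fast cation capture,
* :func:`borderline_model` — both pathways competing (five steps).

Only integer reaction orders are allowed: every step is an elementary
event of molecularity 1 or 2, and its rate is ``k(T) * prod[reactant]``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "R_GAS",
    "T_REF",
    "ArrheniusParams",
    "Species",
    "ElementaryStep",
    "KineticModel",
    "ModelDefinitionError",
    "rate_constant",
    "sn2_model",
    "sn1_model",
    "borderline_model",
    "builtin_model",
    "BUILTIN_MODELS",
    "CAPTURE_RATE_FIXED",
]

#: Gas constant, J/(mol K).
R_GAS = 8.314

#: Reference temperature for the (k_ref, Ea) parameterization, kelvin (25 degC).
T_REF = 298.15


class ModelDefinitionError(ValueError):
    """Raised when a model, step or parameter set is ill-formed."""


@dataclass(frozen=True)
class ArrheniusParams:
    """Arrhenius rate parameters ``k(T) = A * exp(-Ea / (R T))``.

    Parameters
    ----------
    A : float
        Pre-exponential factor.  Units follow the step molecularity:
        1/s for unimolecular, L/(mol s) for bimolecular steps.
    Ea : float
        Activation energy in J/mol, non-negative.
    """

    A: float
    Ea: float

    def __post_init__(self) -> None:
        # A == 0 is allowed as the degenerate "switched-off step" used to
        # reduce the borderline model to a single-mechanism model.
        if self.A < 0:
            raise ModelDefinitionError(f"pre-exponential factor must be >= 0, got {self.A}")
        if self.Ea < 0:
            raise ModelDefinitionError(f"activation energy must be >= 0, got {self.Ea}")

    @classmethod
    def from_kref(cls, k_ref: float, Ea: float, T_ref: float = T_REF) -> "ArrheniusParams":
        """Build from a rate constant at a reference temperature.

        ``A`` is recovered algebraically as ``k_ref * exp(Ea / (R T_ref))``.
        This parameterization decorrelates the fitted parameters compared
        to raw ``(A, Ea)``.
        """
        if k_ref < 0:
            raise ModelDefinitionError(f"k_ref must be >= 0, got {k_ref}")
        return cls(A=k_ref * math.exp(Ea / (R_GAS * T_ref)), Ea=Ea)

    def k(self, T: float) -> float:
        """Rate constant at absolute temperature ``T`` (kelvin)."""
        return rate_constant(self, T)

    def k_ref(self, T_ref: float = T_REF) -> float:
        """Rate constant at the reference temperature."""
        return rate_constant(self, T_ref)


def rate_constant(params: ArrheniusParams, T: float) -> float:
    """Evaluate the Arrhenius law ``A * exp(-Ea/(R T))`` at ``T`` kelvin.

    Strictly increasing in ``T`` whenever ``Ea > 0``.
    """
    if not T > 0:
        raise ValueError(f"absolute temperature must be > 0 K, got {T}")
    return params.A * math.exp(-params.Ea / (R_GAS * T))


@dataclass(frozen=True)
class Species:
    """A chemical species tracked by the model.

    ``observable`` marks species quantified in the time-course data
    (by HPLC conversion yield); transient intermediates such as the
    benzyl cation are not observable.
    """

    name: str
    role: str = "reactant"  # reactant | intermediate | product | reagent
    observable: bool = True

    _ROLES = ("reactant", "intermediate", "product", "reagent")

    def __post_init__(self) -> None:
        if not self.name:
            raise ModelDefinitionError("species name must be non-empty")
        if self.role not in self._ROLES:
            raise ModelDefinitionError(
                f"species role must be one of {self._ROLES}, got {self.role!r}"
            )


@dataclass(frozen=True)
class ElementaryStep:
    """A single mass-action elementary step.

    Stoichiometric coefficients are positive integers and the
    molecularity (sum of reactant coefficients) must be 1 or 2 —
    elementary events of higher molecularity are not physical, and
    fractional orders are excluded by construction.
    """

    reactants: dict[str, int]
    products: dict[str, int]
    rate_params: ArrheniusParams
    label: str = ""

    def __post_init__(self) -> None:
        if not self.reactants or not self.products:
            raise ModelDefinitionError(f"step {self.label!r}: needs >=1 reactant and product")
        for side, coeffs in (("reactant", self.reactants), ("product", self.products)):
            for name, nu in coeffs.items():
                if not (isinstance(nu, int) and nu > 0):
                    raise ModelDefinitionError(
                        f"step {self.label!r}: {side} {name!r} has non-positive-integer "
                        f"coefficient {nu!r} (integer orders only)"
                    )
        if self.molecularity not in (1, 2):
            raise ModelDefinitionError(
                f"step {self.label!r}: molecularity {self.molecularity} not in (1, 2)"
            )

    @property
    def molecularity(self) -> int:
        return sum(self.reactants.values())

    def net_stoichiometry(self, name: str) -> int:
        """Signed stoichiometric change of ``name`` in this step."""
        return self.products.get(name, 0) - self.reactants.get(name, 0)


@dataclass
class KineticModel:
    """Species + elementary steps + linear conservation laws.

    ``conservation_checks`` maps a label to ``{species: coefficient}``;
    the weighted concentration sum must be constant along any trajectory
    and is used as an integrator-accuracy oracle.
    """

    name: str
    species: list[Species]
    steps: list[ElementaryStep]
    conservation_checks: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        names = [s.name for s in self.species]
        if len(names) != len(set(names)):
            raise ModelDefinitionError(f"model {self.name!r}: duplicate species names")
        if not any(s.observable for s in self.species):
            raise ModelDefinitionError(f"model {self.name!r}: no observable species")
        known = set(names)
        for step in self.steps:
            for name in (*step.reactants, *step.products):
                if name not in known:
                    raise ModelDefinitionError(
                        f"model {self.name!r}: step {step.label!r} references unknown "
                        f"species {name!r}"
                    )
        for label, coeffs in self.conservation_checks.items():
            for name in coeffs:
                if name not in known:
                    raise ModelDefinitionError(
                        f"model {self.name!r}: conservation {label!r} references unknown "
                        f"species {name!r}"
                    )

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def observable_names(self) -> list[str]:
        return [s.name for s in self.species if s.observable]

    def step(self, label: str) -> ElementaryStep:
        for s in self.steps:
            if s.label == label:
                return s
        raise KeyError(f"model {self.name!r} has no step labelled {label!r}")

    def with_rate_params(self, params: dict[str, ArrheniusParams]) -> "KineticModel":
        """Copy of the model with rate parameters replaced by step label."""
        unknown = set(params) - {s.label for s in self.steps}
        if unknown:
            raise KeyError(f"unknown step labels: {sorted(unknown)}")
        steps = [
            replace(s, rate_params=params.get(s.label, s.rate_params)) for s in self.steps
        ]
        return KineticModel(
            name=self.name,
            species=list(self.species),
            steps=steps,
            conservation_checks={k: dict(v) for k, v in self.conservation_checks.items()},
        )

    def rate_params_by_label(self) -> dict[str, ArrheniusParams]:
        return {s.label: s.rate_params for s in self.steps}

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "species": [
                {"name": s.name, "role": s.role, "observable": s.observable}
                for s in self.species
            ],
            "steps": [
                {
                    "label": s.label,
                    "reactants": dict(s.reactants),
                    "products": dict(s.products),
                    "A": s.rate_params.A,
                    "Ea": s.rate_params.Ea,
                }
                for s in self.steps
            ],
            "conservation_checks": {
                k: dict(v) for k, v in self.conservation_checks.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticModel":
        return cls(
            name=d["name"],
            species=[Species(**s) for s in d["species"]],
            steps=[
                ElementaryStep(
                    reactants={k: int(v) for k, v in s["reactants"].items()},
                    products={k: int(v) for k, v in s["products"].items()},
                    rate_params=ArrheniusParams(A=float(s["A"]), Ea=float(s["Ea"])),
                    label=s.get("label", ""),
                )
                for s in d["steps"]
            ],
            conservation_checks={
                k: {n: float(c) for n, c in v.items()}
                for k, v in d.get("conservation_checks", {}).items()
            },
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "KineticModel":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "KineticModel":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Built-in benzylation models
# ---------------------------------------------------------------------------

#: Fixed mono-capture rate constant for the cation, L/(mol s).  Cation
#: capture by the amine is treated as diffusion-fast and barrierless
#: (Ea = 0); only the di/mono capture ratio is a meaningful (fittable)
#: quantity when capture is much faster than ionization.
CAPTURE_RATE_FIXED = 1.0e3

#: Default rate parameters, as (k at 298.15 K, Ea in J/mol).  These are
#: synthetic reference values used by the built-in factories and the
#: synthetic-study generator: the two branches contribute comparably
#: around 30-40 degC and the bimolecular branch is the more
#: temperature-sensitive (higher Ea), so the mechanism balance tilts
#: toward ionization when cold and toward direct substitution when hot.
DEFAULT_RATE_PARAMS: dict[str, tuple[float, float]] = {
    "sn2_mono": (1.0e-3, 85.0e3),
    "sn2_di": (5.0e-4, 88.0e3),
    "ionization": (8.0e-4, 38.0e3),
    "capture_mono": (CAPTURE_RATE_FIXED, 0.0),
    "capture_di": (1.2 * CAPTURE_RATE_FIXED, 0.0),
}


def _default_params(label: str, overrides: dict[str, ArrheniusParams] | None) -> ArrheniusParams:
    if overrides and label in overrides:
        return overrides[label]
    k_ref, Ea = DEFAULT_RATE_PARAMS[label]
    return ArrheniusParams.from_kref(k_ref, Ea)


def _benzylation_species() -> list[Species]:
    return [
        Species("1", role="reactant", observable=True),
        Species("BnBr", role="reagent", observable=False),
        Species("2", role="product", observable=True),
        Species("di-2", role="product", observable=True),
        Species("BnCation", role="intermediate", observable=False),
    ]


def _benzylation_conservation() -> dict[str, dict[str, float]]:
    # The di-product carries two benzyl groups.
    return {
        "aniline_moiety": {"1": 1.0, "2": 1.0, "di-2": 1.0},
        "benzyl_moiety": {"BnBr": 1.0, "BnCation": 1.0, "2": 1.0, "di-2": 2.0},
    }


def _sn2_steps(overrides: dict[str, ArrheniusParams] | None) -> list[ElementaryStep]:
    return [
        ElementaryStep(
            reactants={"1": 1, "BnBr": 1},
            products={"2": 1},
            rate_params=_default_params("sn2_mono", overrides),
            label="sn2_mono",
        ),
        ElementaryStep(
            reactants={"2": 1, "BnBr": 1},
            products={"di-2": 1},
            rate_params=_default_params("sn2_di", overrides),
            label="sn2_di",
        ),
    ]


def _sn1_steps(overrides: dict[str, ArrheniusParams] | None) -> list[ElementaryStep]:
    return [
        ElementaryStep(
            reactants={"BnBr": 1},
            products={"BnCation": 1},
            rate_params=_default_params("ionization", overrides),
            label="ionization",
        ),
        ElementaryStep(
            reactants={"BnCation": 1, "1": 1},
            products={"2": 1},
            rate_params=_default_params("capture_mono", overrides),
            label="capture_mono",
        ),
        ElementaryStep(
            reactants={"BnCation": 1, "2": 1},
            products={"di-2": 1},
            rate_params=_default_params("capture_di", overrides),
            label="capture_di",
        ),
    ]


def sn2_model(rate_params: dict[str, ArrheniusParams] | None = None) -> KineticModel:
    """Concerted bimolecular substitution: two consecutive SN2 steps.

    ``1 + BnBr -> 2`` then ``2 + BnBr -> di-2``; both rate constants in
    L/(mol s).
    """
    return KineticModel(
        name="sn2",
        species=_benzylation_species(),
        steps=_sn2_steps(rate_params),
        conservation_checks=_benzylation_conservation(),
    )


def sn1_model(rate_params: dict[str, ArrheniusParams] | None = None) -> KineticModel:
    """Stepwise substitution through a benzyl cation.

    Rate-determining unimolecular ionization ``BnBr -> BnCation``
    (rate constant in 1/s, irreversible — no common-ion return) followed
    by fast bimolecular capture by aniline or the mono-product.
    """
    return KineticModel(
        name="sn1",
        species=_benzylation_species(),
        steps=_sn1_steps(rate_params),
        conservation_checks=_benzylation_conservation(),
    )


def borderline_model(rate_params: dict[str, ArrheniusParams] | None = None) -> KineticModel:
    """Both substitution pathways competing on the same substrate.

    The union of the SN2 and SN1 step sets over the shared species set:
    five elementary steps in total.  Zeroing one branch's rate constants
    reduces the model exactly to the other single-mechanism model.
    """
    return KineticModel(
        name="borderline",
        species=_benzylation_species(),
        steps=_sn2_steps(rate_params) + _sn1_steps(rate_params),
        conservation_checks=_benzylation_conservation(),
    )


BUILTIN_MODELS = {
    "sn2": sn2_model,
    "sn1": sn1_model,
    "borderline": borderline_model,
}


def builtin_model(
    name: str, rate_params: dict[str, ArrheniusParams] | None = None
) -> KineticModel:
    """Look up a built-in model factory by name (``sn1``/``sn2``/``borderline``)."""
    try:
        factory = BUILTIN_MODELS[name]
    except KeyError:
        raise ModelDefinitionError(
            f"unknown model {name!r}; built-ins: {sorted(BUILTIN_MODELS)}"
        ) from None
    return factory(rate_params)
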