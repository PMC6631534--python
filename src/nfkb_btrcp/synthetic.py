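"""Parameter fixtures and synthetic test signals.

The packaged YAML fixture carries the base-model rate constants (µM, s).
`crosscheck_sbml` compares a loaded :class:`ParameterSet` against an SBML
Level 2/3 encoding of the base model and aborts with a per-parameter diff
when any value deviates by more than a relative tolerance.

Synthetic signals provide closed-form ground truth for the measure
estimators: an erf step whose derivative is a Gaussian bump centered at
``center`` with width ``width`` has signaling time = center and signal
duration = width exactly; sinusoids have a known period; a constant
signal leaves the moment measures undefined. Additive Gaussian noise
(seeded) stresses the estimators; the model itself is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from lxml import etree
from scipy.special import erf

from .model import ConfigurationError, DomainError, ParameterSet

__all__ = [
    "packaged_fixture_path",
    "load_parameter_fixture",
    "write_parameter_fixture",
    "crosscheck_sbml",
    "SyntheticSignalSpec",
    "generate_signal",
]

_FIXTURE_NAME = "lipniacki2004_params.yaml"


def packaged_fixture_path():
    """Path-like handle to the packaged base-model parameter fixture."""
    return resources.files("nfkb_btrcp") / "data" / _FIXTURE_NAME


def load_parameter_fixture(path=None) -> ParameterSet:
    """Load and validate a flat YAML parameter file (Document-S1 units).

    Defaults to the packaged base-model fixture. Missing, unknown or
    negative entries raise :class:`ConfigurationError` naming the key.
    """
    src = packaged_fixture_path() if path is None else path
    if hasattr(src, "read_text"):
        text = src.read_text()
    else:
        with open(src) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"parameter file {src} is not a flat mapping")
    return ParameterSet.from_dict(raw)


def write_parameter_fixture(params: ParameterSet, path) -> None:
    """Write a parameter set as flat YAML; round-trips bit-identically
    through :func:`load_parameter_fixture` (repr-exact floats)."""
    with open(path, "w") as fh:
        for k, v in params.to_dict().items():
            fh.write(f"{k}: {v!r}\n")


def crosscheck_sbml(params: ParameterSet, sbml_path,
                    rel_tol: float = 1.0e-6) -> dict[str, float]:
    """Compare a parameter set against an SBML base-model encoding.

    Reads the global ``<parameter>`` elements of an SBML Level 2/3 file
    (namespace-agnostic) and compares every id that matches a rate-constant
    name, plus ``kv`` and ``nf_total`` if present. Returns the mapping of
    compared ids to relative deviations; any deviation > ``rel_tol``
    aborts with a diff report.
    """
    tree = etree.parse(str(sbml_path))
    sbml_values: dict[str, float] = {}
    for el in tree.iter():
        if etree.QName(el).localname == "parameter" and el.get("id") is not None:
            val = el.get("value")
            if val is not None:
                sbml_values[el.get("id")] = float(val)
    ours = params.to_dict()
    compared: dict[str, float] = {}
    mismatches: list[str] = []
    for key, sv in sbml_values.items():
        if key not in ours:
            continue
        ov = ours[key]
        denom = max(abs(sv), abs(ov), 1.0e-300)
        rel = abs(sv - ov) / denom if (sv != 0 or ov != 0) else 0.0
        compared[key] = rel
        if rel > rel_tol:
            mismatches.append(f"  {key}: fixture={ov!r} sbml={sv!r} rel_dev={rel:.3e}")
    if not compared:
        raise ConfigurationError(f"no comparable parameters found in {sbml_path}")
    if mismatches:
        raise ConfigurationError(
            "parameter fixture disagrees with SBML base model "
            f"(rel tol {rel_tol:g}):\n" + "\n".join(mismatches)
        )
    return compared


_FAMILIES = ("gaussian-bump-derivative", "sinusoid", "damped-sinusoid", "constant")


@dataclass(frozen=True)
class SyntheticSignalSpec:
    """A deterministic analytic test signal plus optional seeded noise.

    Families:

    * ``gaussian-bump-derivative`` — offset + amplitude·Φ((t−center)/width):
      |derivative| is a Gaussian bump, so signaling time = center and
      signal duration = width analytically.
    * ``sinusoid`` — offset + amplitude·sin(2πt/period).
    * ``damped-sinusoid`` — the same with envelope exp(−damping·t).
    * ``constant`` — offset everywhere.
    """

    family: str
    t_final: float = 630.0    # min
    dt: float = 0.5           # min
    amplitude: float = 1.0    # nM
    offset: float = 0.0       # nM
    center: float = 200.0     # min (gaussian-bump-derivative)
    width: float = 30.0       # min (gaussian-bump-derivative)
    period: float = 100.0     # min (sinusoids)
    damping: float = 0.0      # 1/min (damped-sinusoid)
    noise_sd: float = 0.0     # nM
    seed: int = 42

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise DomainError(f"family must be one of {_FAMILIES}")
        if self.width <= 0 or self.period <= 0 or self.dt <= 0:
            raise DomainError("width, period and dt must be > 0")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")


def generate_signal(spec: SyntheticSignalSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sample the specified signal; reproducible given the seed.

    Returns (t_min, y_nM) on a uniform grid covering [0, t_final].
    """
    t = np.arange(0.0, spec.t_final + spec.dt / 2, spec.dt)
    if spec.family == "constant":
        y = np.full_like(t, spec.offset)
    elif spec.family == "gaussian-bump-derivative":
        z = (t - spec.center) / (spec.width * np.sqrt(2.0))
        y = spec.offset + spec.amplitude * 0.5 * (1.0 + erf(z))
    elif spec.family == "sinusoid":
        y = spec.offset + spec.amplitude * np.sin(2.0 * np.pi * t / spec.period)
    else:  # damped-sinusoid
        y = spec.offset + spec.amplitude * np.exp(-spec.damping * t) * np.sin(
            2.0 * np.pi * t / spec.period)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=t.size)
    return t, y
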