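"""Core reaction network of canonical NF-κB signaling with β-TrCP-regulated IκB degradation.

The network is the Lipniacki-type two-feedback (IκBα, A20) model of
TNF-induced NF-κB activation: three IKK forms (neutral, active, inactive),
cytoplasmic and nuclear pools of NF-κB and IκBα, their complexes, and the
NF-κB-induced transcripts for IκBα, A20 and a generic control gene (cgen).
TNF enters as a binary on/off input. The extension adds the E3-ligase
substrate receptor β-TrCP, which mediates ubiquitination of
IKK-phosphorylated IκB: the two IKK-dependent IκB degradation reactions
(numbers 8 and 10 in the reaction scheme) are scaled by the dimensionless
factor (β-TrCP / 1 nM). At 1 nM β-TrCP the extended model reduces exactly
to the unextended base model.

Units
-----
Rate constants are kept in the units of the published base model, µM and
seconds. The public surface (states, trajectories, β-TrCP levels) uses nM
and minutes, the scales on which all results are reported. Nuclear species
are simulated per nuclear volume; the convenience readouts
(:meth:`StateVector.nuclear_nfkb`) additionally express nuclear NF-κB as a
whole-cell-equivalent concentration (per-nucleus value divided by the
cytoplasm/nucleus volume ratio ``kv``), which is the scale of all reported
nuclear concentrations (0.46 nM resting, ~56 nM first peak, ...).

The 15 species are reduced to 14 ODEs by eliminating free cytoplasmic
NF-κB through the conservation of total NF-κB.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Callable, Mapping, Union

import numpy as np

__all__ = [
    "SPECIES",
    "ODE_SPECIES",
    "N_REACTIONS",
    "ParameterSet",
    "StateVector",
    "Stimulus",
    "ConfigurationError",
    "DomainError",
    "reaction_rates",
    "ode_rhs",
    "species_derivatives",
    "jacobian_matrix",
    "total_nfkb",
]

#: the 15 model species, in canonical order
SPECIES = (
    "IKKn",            # neutral IKK
    "IKKa",            # active IKK
    "IKKi",            # inactive IKK
    "IKKa_IkBa",       # active-IKK · IκBα complex
    "IKKa_IkBa_NFkB",  # active-IKK · IκBα · NF-κB complex
    "NFkB",            # free cytoplasmic NF-κB
    "IkBa",            # free cytoplasmic IκBα
    "IkBa_NFkB",       # cytoplasmic IκBα · NF-κB complex
    "NFkBn",           # nuclear NF-κB
    "IkBan",           # nuclear IκBα
    "IkBan_NFkBn",     # nuclear IκBα · NF-κB complex
    "A20",             # A20 protein
    "A20t",            # A20 mRNA
    "IkBat",           # IκBα mRNA
    "cgent",           # control-gene mRNA
)

#: index of the species eliminated by the NF-κB conservation relation
_I_NFKB = SPECIES.index("NFkB")

#: the 14 integrated species (free cytoplasmic NF-κB eliminated)
ODE_SPECIES = tuple(s for s in SPECIES if s != "NFkB")

#: species carrying one NF-κB moiety, and the conservation weight of each
#: (nuclear pools are weighted by 1/kv: concentrations per nuclear volume
#: convert to whole-cell amounts through the volume ratio)
NFKB_POOLS = ("NFkB", "IKKa_IkBa_NFkB", "IkBa_NFkB", "NFkBn", "IkBan_NFkBn")
_NUCLEAR = ("NFkBn", "IkBan", "IkBan_NFkBn")

N_REACTIONS = 28

NM_PER_UM = 1.0e3
S_PER_MIN = 60.0


class ConfigurationError(ValueError):
    """A parameter set or scenario configuration is incomplete or invalid."""


class DomainError(ValueError):
    """An input lies outside the model's domain (e.g. negative concentration)."""


# rate constants of the base model (Document-S1 symbols), µM and seconds
_RATE_CONSTANTS = (
    "kprod", "kdeg", "k1", "k2", "k3",
    "a1", "a2", "a3", "t1", "t2",
    "c1", "c2", "c3", "c4", "c5",
    "c1a", "c2a", "c3a", "c4a", "c5a", "c6a",
    "c1c", "c2c", "c3c",
    "i1", "e2a", "i1a", "e1a",
)


@dataclass(frozen=True)
class ParameterSet:
    """All constants of the extended model, in base-model units (µM, s).

    ``kv`` is the cytoplasmic-to-nuclear volume ratio, ``nf_total`` the
    conserved total NF-κB concentration (µM, whole-cell basis) and
    ``btrcp_ref`` the β-TrCP reference concentration (µM) at which the
    extension reduces to the base model (1 nM).
    """

    kprod: float   # constitutive IKKn production (µM/s)           reaction 1
    kdeg: float    # degradation of all IKK forms (1/s)            reactions 2, 5, 6
    k1: float      # TNF-dependent IKKn activation (1/s)           reaction 3
    k2: float      # TNF- and A20-dependent IKKa inactivation (1/(µM·s)), reaction 26
    k3: float      # spontaneous IKKa inactivation (1/s)           reaction 4
    a1: float      # IκBα–NF-κB association, both compartments (1/(µM·s)), reactions 12, 14
    a2: float      # IKKa–IκBα association (1/(µM·s))              reaction 9
    a3: float      # IKKa–(IκBα·NF-κB) association (1/(µM·s))      reaction 7
    t1: float      # IκBα degradation in IKKa·IκBα, β-TrCP-scaled (1/s), reaction 8
    t2: float      # IκBα degradation in IKKa·IκBα·NF-κB, β-TrCP-scaled (1/s), reaction 10
    c1: float      # NF-κB-induced A20 transcription (1/s)         reaction 22
    c2: float      # constitutive A20 transcription (µM/s)         reaction 22
    c3: float      # A20 mRNA degradation (1/s)                    reaction 23
    c4: float      # A20 translation (1/s)                         reaction 24
    c5: float      # A20 protein degradation (1/s)                 reaction 25
    c1a: float     # NF-κB-induced IκBα transcription (1/s)        reaction 18
    c2a: float     # constitutive IκBα transcription (µM/s)        reaction 18
    c3a: float     # IκBα mRNA degradation (1/s)                   reaction 19
    c4a: float     # IκBα translation (1/s)                        reaction 20
    c5a: float     # free IκBα degradation (1/s)                   reaction 15
    c6a: float     # IκBα degradation inside IκBα·NF-κB (1/s)      reaction 21
    c1c: float     # NF-κB-induced cgen transcription (1/s)        reaction 27
    c2c: float     # constitutive cgen transcription (µM/s)        reaction 27
    c3c: float     # cgen mRNA degradation (1/s)                   reaction 28
    i1: float      # NF-κB nuclear import (1/s)                    reaction 11
    e2a: float     # IκBα·NF-κB nuclear export (1/s)               reaction 13
    i1a: float     # IκBα nuclear import (1/s)                     reaction 16
    e1a: float     # IκBα nuclear export (1/s)                     reaction 17
    kv: float        # cytoplasmic-to-nuclear volume ratio (dimensionless)
    nf_total: float  # conserved total NF-κB (µM)
    btrcp_ref: float = 1.0e-3  # β-TrCP reference concentration (µM) = 1 nM

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ConfigurationError(f"parameter {f.name!r} is not finite: {v!r}")
            if v < 0:
                raise ConfigurationError(f"parameter {f.name!r} must be >= 0, got {v}")
        if self.kv <= 0:
            raise ConfigurationError("volume ratio kv must be > 0")
        if self.nf_total <= 0:
            raise ConfigurationError("total NF-κB nf_total must be > 0")
        if self.btrcp_ref <= 0:
            raise ConfigurationError("btrcp_ref must be > 0")

    @classmethod
    def from_dict(cls, values: Mapping[str, float]) -> "ParameterSet":
        """Build from a flat mapping; fail loudly on missing or extra keys."""
        expected = {f.name for f in fields(cls)}
        got = set(values)
        missing = sorted(expected - got - {"btrcp_ref"})
        extra = sorted(got - expected)
        if missing:
            raise ConfigurationError(f"missing parameter(s): {', '.join(missing)}")
        if extra:
            raise ConfigurationError(f"unknown parameter(s): {', '.join(extra)}")
        return cls(**{k: float(v) for k, v in values.items()})

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @property
    def rate_constants(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in _RATE_CONSTANTS}


@dataclass(frozen=True)
class Stimulus:
    """External inputs: binary TNF and the β-TrCP level.

    ``tnf`` is the TNF indicator that applies for t >= 0; the pre-stimulus
    history is always TNF = 0 (switching happens at t = 0 exactly).
    ``btrcp_nM`` is the baseline β-TrCP concentration in nM. ``drug`` is an
    optional time-dependent modulation (any object exposing
    ``factor(t_min) -> float``, see :mod:`nfkb_btrcp.perturbation`); the
    effective scaling of reactions 8 and 10 at time t is
    ``(btrcp_nM / 1 nM) * drug.factor(t)``.
    """

    tnf: int
    btrcp_nM: float
    drug: object | None = None

    def __post_init__(self) -> None:
        if self.tnf not in (0, 1):
            raise DomainError(f"TNF indicator must be 0 or 1, got {self.tnf!r}")
        if self.btrcp_nM < 0:
            raise DomainError(f"β-TrCP level must be >= 0 nM, got {self.btrcp_nM}")

    def btrcp_factor(self, t_min: float, params: ParameterSet) -> float:
        """Dimensionless multiplier on reactions 8 and 10 at time ``t_min``."""
        base = (self.btrcp_nM / NM_PER_UM) / params.btrcp_ref
        if self.drug is None:
            return base
        f = base * float(self.drug.factor(t_min))
        if f < 0:
            raise DomainError("effective β-TrCP scaling became negative")
        return f

    def breakpoints(self, t_final_min: float) -> tuple[float, ...]:
        """Interior discontinuity times of the input on (0, t_final), sorted."""
        if self.drug is None:
            return ()
        pts = getattr(self.drug, "breakpoints", lambda: ())()
        return tuple(sorted(p for p in pts if 0.0 < p < t_final_min))


@dataclass
class StateVector:
    """Concentrations of the 15 model species at one time point, in nM.

    Cytoplasmic species are concentrations per cytoplasmic volume, nuclear
    species (NFkBn, IkBan, IkBan_NFkBn) per nuclear volume, exactly as the
    model integrates them.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(SPECIES),):
            raise DomainError(
                f"state must have {len(SPECIES)} entries, got {self.values.shape}"
            )

    def __getitem__(self, species: str) -> float:
        return float(self.values[SPECIES.index(species)])

    @classmethod
    def from_dict(cls, conc_nM: Mapping[str, float]) -> "StateVector":
        missing = [s for s in SPECIES if s not in conc_nM]
        if missing:
            raise ConfigurationError(f"state missing species: {', '.join(missing)}")
        return cls(np.array([conc_nM[s] for s in SPECIES], dtype=float))

    def to_dict(self) -> dict[str, float]:
        return dict(zip(SPECIES, self.values))

    def nuclear_nfkb(self, params: ParameterSet) -> float:
        """Nuclear NF-κB as a whole-cell-equivalent concentration (nM).

        This is the per-nucleus concentration divided by the volume ratio
        ``kv`` — the scale on which nuclear NF-κB is reported (resting
        ~0.46 nM, first peak ~56 nM at 1 nM β-TrCP).
        """
        return self["NFkBn"] / params.kv

    def total_nfkb(self, params: ParameterSet) -> float:
        """Conserved total NF-κB (nM), nuclear pools weighted by 1/kv."""
        return total_nfkb(self.values, params)

    def validate(self, params: ParameterSet, atol_nM: float = 1.0e-6) -> None:
        """Check non-negativity and the NF-κB conservation relation."""
        if np.any(self.values < -1.0e-9):
            bad = [s for s, v in zip(SPECIES, self.values) if v < -1.0e-9]
            raise DomainError(f"negative concentration(s): {', '.join(bad)}")
        tot = self.total_nfkb(params)
        expect = params.nf_total * NM_PER_UM
        if abs(tot - expect) > atol_nM:
            raise DomainError(
                f"NF-κB conservation violated: total {tot:.6g} nM != {expect:.6g} nM"
            )


def total_nfkb(values_nM: np.ndarray, params: ParameterSet) -> float:
    """Conservation-weighted total NF-κB of a 15-species state (nM)."""
    v = np.asarray(values_nM, dtype=float)
    tot = 0.0
    for s in NFKB_POOLS:
        w = 1.0 / params.kv if s in _NUCLEAR else 1.0
        tot += w * v[SPECIES.index(s)]
    return tot


# ---------------------------------------------------------------------------
# internal fast paths (µM, s); x is the 14-vector of integrated species
# in ODE_SPECIES order
# ---------------------------------------------------------------------------

def _free_nfkb(x: np.ndarray, p: ParameterSet) -> float:
    # conservation: NFkB = NFtot - IKKa·IkBa·NFkB - IkBa·NFkB - (NFkBn + Cn)/kv
    return p.nf_total - x[4] - x[6] - (x[7] + x[9]) / p.kv


def _rates28(x: np.ndarray, p: ParameterSet, tr: float, b: float,
             N: float | None = None) -> np.ndarray:
    """The 28 reaction rates (µM/s, cytoplasmic-volume basis) at a 14-state.

    ``N`` is the free cytoplasmic NF-κB concentration; by default it is
    reconstructed from the conservation relation (the reduced-ODE path),
    but callers evaluating rate laws on an explicit 15-species state pass
    the state's own value.
    """
    IKKn, IKKa, IKKi, TK, TKN, IkBa, C, Nn, IkBan, Cn, A20, A20t, IkBat, cgent = x
    if N is None:
        N = _free_nfkb(x, p)
    r = np.empty(N_REACTIONS)
    r[0] = p.kprod                    # 1  IKKn production
    r[1] = p.kdeg * IKKn              # 2  IKKn degradation
    r[2] = tr * p.k1 * IKKn           # 3  TNF-dependent IKKn -> IKKa
    r[3] = p.k3 * IKKa                # 4  spontaneous IKKa -> IKKi
    r[4] = p.kdeg * IKKa              # 5  IKKa degradation
    r[5] = p.kdeg * IKKi              # 6  IKKi degradation
    r[6] = p.a3 * IKKa * C            # 7  IKKa + IkBa·NFkB association
    r[7] = b * p.t1 * TK              # 8  IkBa degradation in IKKa·IkBa   (β-TrCP)
    r[8] = p.a2 * IKKa * IkBa         # 9  IKKa + IkBa association
    r[9] = b * p.t2 * TKN             # 10 IkBa degradation in ternary cx  (β-TrCP)
    r[10] = p.i1 * N                  # 11 NF-κB nuclear import
    r[11] = p.a1 * IkBan * Nn         # 12 nuclear IkBa–NFkB association
    r[12] = p.e2a * Cn                # 13 nuclear complex export
    r[13] = p.a1 * IkBa * N           # 14 cytoplasmic IkBa–NFkB association
    r[14] = p.c5a * IkBa              # 15 free IkBa degradation
    r[15] = p.i1a * IkBa              # 16 IkBa nuclear import
    r[16] = p.e1a * IkBan             # 17 IkBa nuclear export
    r[17] = p.c2a + p.c1a * Nn        # 18 IkBa transcription
    r[18] = p.c3a * IkBat             # 19 IkBa mRNA degradation
    r[19] = p.c4a * IkBat             # 20 IkBa translation
    r[20] = p.c6a * C                 # 21 IkBa degradation inside IkBa·NFkB
    r[21] = p.c2 + p.c1 * Nn          # 22 A20 transcription
    r[22] = p.c3 * A20t               # 23 A20 mRNA degradation
    r[23] = p.c4 * A20t               # 24 A20 translation
    r[24] = p.c5 * A20                # 25 A20 degradation
    r[25] = tr * p.k2 * IKKa * A20    # 26 TNF- and A20-dependent IKKa inactivation
    r[26] = p.c2c + p.c1c * Nn        # 27 cgen transcription
    r[27] = p.c3c * cgent             # 28 cgen mRNA degradation
    return r


def _assemble14(r: np.ndarray, kv: float) -> np.ndarray:
    """Signed sums of reaction rates for the 14 integrated species.

    Transport between compartments carries the volume-ratio factor: a flux
    that changes a cytoplasmic concentration by r changes the corresponding
    nuclear concentration by kv*r.
    """
    dx = np.empty(14)
    dx[0] = r[0] - r[1] - r[2]                                   # IKKn
    dx[1] = r[2] - r[3] - r[4] - r[25] - r[8] + r[7] - r[6] + r[9]  # IKKa
    dx[2] = r[3] + r[25] - r[5]                                  # IKKi
    dx[3] = r[8] - r[7]                                          # IKKa_IkBa
    dx[4] = r[6] - r[9]                                          # IKKa_IkBa_NFkB
    dx[5] = -r[8] - r[13] - r[14] + r[19] - r[15] + r[16]        # IkBa
    dx[6] = r[13] - r[20] - r[6] + r[12]                         # IkBa_NFkB
    dx[7] = kv * r[10] - r[11]                                   # NFkBn
    dx[8] = kv * r[15] - kv * r[16] - r[11]                      # IkBan
    dx[9] = r[11] - kv * r[12]                                   # IkBan_NFkBn
    dx[10] = r[23] - r[24]                                       # A20
    dx[11] = r[21] - r[22]                                       # A20t
    dx[12] = r[17] - r[18]                                       # IkBat
    dx[13] = r[26] - r[27]                                       # cgent
    return dx


def _rhs14(x: np.ndarray, p: ParameterSet, tr: float, b: float) -> np.ndarray:
    """Time derivatives (µM/s) of the 14 integrated species (reduced system)."""
    return _assemble14(_rates28(x, p, tr, b), p.kv)


def _jac14(x: np.ndarray, p: ParameterSet, tr: float, b: float) -> np.ndarray:
    """Analytic Jacobian (1/s) of :func:`_rhs14` w.r.t. the 14 states.

    Eliminated free NF-κB contributes through the chain rule with
    ∂N/∂TKN = ∂N/∂C = -1 and ∂N/∂NFkBn = ∂N/∂Cn = -1/kv.
    """
    IKKn, IKKa, IKKi, TK, TKN, IkBa, C, Nn, IkBan, Cn, A20, A20t, IkBat, cgent = x
    N = _free_nfkb(x, p)
    kv = p.kv
    J = np.zeros((14, 14))
    # IKKn
    J[0, 0] = -p.kdeg - tr * p.k1
    # IKKa
    J[1, 0] = tr * p.k1
    J[1, 1] = -p.k3 - p.kdeg - tr * p.k2 * A20 - p.a2 * IkBa - p.a3 * C
    J[1, 3] = b * p.t1
    J[1, 4] = b * p.t2
    J[1, 5] = -p.a2 * IKKa
    J[1, 6] = -p.a3 * IKKa
    J[1, 10] = -tr * p.k2 * IKKa
    # IKKi
    J[2, 1] = p.k3 + tr * p.k2 * A20
    J[2, 2] = -p.kdeg
    J[2, 10] = tr * p.k2 * IKKa
    # IKKa_IkBa
    J[3, 1] = p.a2 * IkBa
    J[3, 3] = -b * p.t1
    J[3, 5] = p.a2 * IKKa
    # IKKa_IkBa_NFkB
    J[4, 1] = p.a3 * C
    J[4, 4] = -b * p.t2
    J[4, 6] = p.a3 * IKKa
    # IkBa: -a2 IKKa IkBa - a1 IkBa N - (c5a+i1a) IkBa + c4a IkBat + e1a IkBan
    J[5, 1] = -p.a2 * IkBa
    J[5, 4] = p.a1 * IkBa            # via ∂N/∂TKN = -1
    J[5, 5] = -p.a2 * IKKa - p.a1 * N - p.c5a - p.i1a
    J[5, 6] = p.a1 * IkBa            # via ∂N/∂C = -1
    J[5, 7] = p.a1 * IkBa / kv       # via ∂N/∂NFkBn
    J[5, 8] = p.e1a
    J[5, 9] = p.a1 * IkBa / kv       # via ∂N/∂Cn
    J[5, 12] = p.c4a
    # IkBa_NFkB: a1 IkBa N - c6a C - a3 IKKa C + e2a Cn
    J[6, 1] = -p.a3 * C
    J[6, 4] = -p.a1 * IkBa
    J[6, 5] = p.a1 * N
    J[6, 6] = -p.c6a - p.a3 * IKKa - p.a1 * IkBa
    J[6, 7] = -p.a1 * IkBa / kv
    J[6, 9] = p.e2a - p.a1 * IkBa / kv
    # NFkBn: kv i1 N - a1 IkBan Nn
    J[7, 4] = -kv * p.i1
    J[7, 6] = -kv * p.i1
    J[7, 7] = -p.i1 - p.a1 * IkBan
    J[7, 8] = -p.a1 * Nn
    J[7, 9] = -p.i1
    # IkBan
    J[8, 5] = kv * p.i1a
    J[8, 7] = -p.a1 * IkBan
    J[8, 8] = -kv * p.e1a - p.a1 * Nn
    # IkBan_NFkBn
    J[9, 7] = p.a1 * IkBan
    J[9, 8] = p.a1 * Nn
    J[9, 9] = -kv * p.e2a
    # A20
    J[10, 10] = -p.c5
    J[10, 11] = p.c4
    # A20t
    J[11, 7] = p.c1
    J[11, 11] = -p.c3
    # IkBat
    J[12, 7] = p.c1a
    J[12, 12] = -p.c3a
    # cgent
    J[13, 7] = p.c1c
    J[13, 13] = -p.c3c
    return J


# ---------------------------------------------------------------------------
# public surface (nM, min) on StateVector
# ---------------------------------------------------------------------------

def _check_state(state: StateVector) -> None:
    if np.any(state.values < -1.0e-9):
        bad = [s for s, v in zip(SPECIES, state.values) if v < -1.0e-9]
        raise DomainError(f"negative concentration(s): {', '.join(bad)}")


def _x14_uM(state: StateVector) -> np.ndarray:
    v = state.values / NM_PER_UM
    return np.delete(v, _I_NFKB)


def reaction_rates(
    state: StateVector,
    params: ParameterSet,
    stimulus: Stimulus,
    t_min: float = 0.0,
) -> np.ndarray:
    """The 28 reaction rates (nM/min, cytoplasmic-volume basis).

    Reactions 3 and 26 scale linearly with the TNF indicator; reactions 8
    and 10 scale linearly with the β-TrCP level (zero at zero β-TrCP, base
    model at 1 nM).
    """
    _check_state(state)
    b = stimulus.btrcp_factor(t_min, params)
    r = _rates28(_x14_uM(state), params, float(stimulus.tnf), b,
                 N=state["NFkB"] / NM_PER_UM)
    return r * NM_PER_UM * S_PER_MIN


def ode_rhs(
    state: StateVector,
    params: ParameterSet,
    stimulus: Stimulus,
    t_min: float = 0.0,
) -> np.ndarray:
    """Time derivatives (nM/min) of the 14 integrated species (ODE_SPECIES order)."""
    _check_state(state)
    b = stimulus.btrcp_factor(t_min, params)
    dx = _rhs14(_x14_uM(state), params, float(stimulus.tnf), b)
    return dx * NM_PER_UM * S_PER_MIN


def species_derivatives(
    state: StateVector,
    params: ParameterSet,
    stimulus: Stimulus,
    t_min: float = 0.0,
) -> np.ndarray:
    """Time derivatives (nM/min) of all 15 species, including free NF-κB.

    All derivatives are assembled from the reaction rates evaluated on the
    state as given (no conservation substitution). The free cytoplasmic
    NF-κB derivative follows its own rate law (released by reactions 10
    and 21, consumed by 11 and 14), so the conservation-weighted sum of
    the five NF-κB-pool derivatives is identically zero.
    """
    r = reaction_rates(state, params, stimulus, t_min)
    dx14 = _assemble14(r, params.kv)
    d_nfkb = r[20] - r[13] + r[9] - r[10]  # reactions 21, 14, 10, 11
    return np.insert(dx14, _I_NFKB, d_nfkb)


def jacobian_matrix(
    state: StateVector,
    params: ParameterSet,
    stimulus: Stimulus,
    t_min: float = 0.0,
) -> np.ndarray:
    """Analytic 14×14 Jacobian ∂(rhs_i)/∂(species_j), in 1/min.

    Rows/columns follow ODE_SPECIES; the conservation-eliminated free
    NF-κB contributes through the chain rule. Concentration units cancel,
    so entries are identical for nM- and µM-based states up to the time
    rescaling.
    """
    _check_state(state)
    b = stimulus.btrcp_factor(t_min, params)
    return _jac14(_x14_uM(state), params, float(stimulus.tnf), b) * S_PER_MIN


def state_from_x14(x14_uM: np.ndarray, params: ParameterSet) -> StateVector:
    """Assemble a full 15-species public state (nM) from an internal 14-state (µM)."""
    v = np.insert(np.asarray(x14_uM, dtype=float), _I_NFKB, _free_nfkb(x14_uM, params))
    return StateVector(v * NM_PER_UM)
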