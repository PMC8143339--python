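"""Core model definitions: parameter types, state layout, and the ODE right-hand side.

The model couples three layers:

1. **Pharmacokinetics** — a one-compartment model with first-order absorption
   (depot ``A``) and elimination (central amount ``X``); serum concentration is
   ``C = X / (Vd/F)``.  Flip-flop kinetics (``ka < ke``) is permitted and is in
   fact the reported regime for GRMS-55 in mice.

2. **Cytokine cascade** — a shared precursor ``T1`` is switched to 1 at the
   moment of the ConA challenge (``cona_time``, default 0.5 h after drug
   dosing) and feeds four transit-compartment pathways that drive
   indirect-response (turnover) models for TNF-α (one pathway compartment),
   IFN-γ (seven), IL-6 (six), and IL-10 (one, with an additional disease-state
   zero-order production that is stimulated by the precursor and linearly
   inhibited by IFN-γ).  The drug attenuates the input to the TNF-α, IFN-γ,
   and IL-6 pathways through an Imax/IC50 inhibitory function.

3. **Disease progression** — ALT and AST turnover stimulated by the excess of
   TNF-α and IFN-γ over their baselines; the ALT driving terms carry power
   exponents α and β (fixed at 1.5), the AST terms are linear.

Every zero-order production constant ``kin`` is derived from the baseline
constraint ``kin = R0 · kout`` so the unperturbed system sits exactly at its
baseline steady state.

Units, fixed package-wide: drug mg·L⁻¹, cytokines ng·L⁻¹, transaminases
U·L⁻¹, time h, doses mg·kg⁻¹ (bioavailability F is folded into Vd/F; drug
amounts are per kg body weight).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DomainError",
    "SchemaError",
    "IntegrationError",
    "NCAError",
    "IdentifiabilityError",
    "PKParameters",
    "CytokinePathwayParameters",
    "IL10Parameters",
    "DiseaseParameters",
    "ModelParameters",
    "STATE_NAMES",
    "STATE_INDEX",
    "N_STATES",
    "OBSERVABLES",
    "inhibition_fraction",
    "kin_from_baseline",
    "pk_concentration",
    "full_rhs",
    "initial_state",
    "observable_index",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class DomainError(ValueError):
    """An argument lies outside the mathematically meaningful domain."""


class SchemaError(ValueError):
    """A table or config does not conform to the expected schema."""


class IntegrationError(RuntimeError):
    """The ODE solver failed or produced non-finite state values."""


class NCAError(ValueError):
    """Non-compartmental analysis cannot be performed on the given data."""


class IdentifiabilityError(ValueError):
    """The experimental design cannot identify the requested parameters."""


# ---------------------------------------------------------------------------
# Parameter types
# ---------------------------------------------------------------------------

def _require_positive(obj, *names):
    for name in names:
        value = getattr(obj, name)
        if not (value > 0):
            raise DomainError(f"{type(obj).__name__}.{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class PKParameters:
    """One-compartment PK parameters (first-order absorption and elimination).

    ``vd_f`` is the apparent volume of distribution Vd/F in L·kg⁻¹ (with
    bioavailability folded in), ``ka`` and ``ke`` are first-order rate
    constants in h⁻¹.  ``ka < ke`` (flip-flop) is legal.
    """

    vd_f: float
    ka: float
    ke: float

    def __post_init__(self):
        _require_positive(self, "vd_f", "ka", "ke")


@dataclass(frozen=True)
class CytokinePathwayParameters:
    """Parameters of one drug-sensitive cytokine pathway (TNF-α, IFN-γ or IL-6).

    ``n_transit`` is the number of pathway-specific transit compartments after
    the shared precursor T1 (1 for TNF-α, 7 for IFN-γ, 6 for IL-6).  ``imax``
    is the maximal inhibition fraction (fixed to 1 in the reported fits),
    ``ic50`` the drug concentration (mg·L⁻¹) of half-maximal inhibition,
    ``s`` the dimensionless linear stimulation coefficient applied to the last
    transit compartment, ``kout`` the first-order loss constant (h⁻¹) and
    ``r0`` the baseline serum concentration (ng·L⁻¹).  The production constant
    kin is never stored; it is always derived as ``r0 * kout``.
    """

    name: str
    n_transit: int
    ic50: float
    s: float
    kout: float
    r0: float
    imax: float = 1.0

    def __post_init__(self):
        _require_positive(self, "ic50", "s", "kout", "r0")
        if not (0.0 <= self.imax <= 1.0):
            raise DomainError(f"imax must lie in [0, 1], got {self.imax!r}")
        if self.n_transit < 1:
            raise DomainError(f"n_transit must be >= 1, got {self.n_transit!r}")

    @property
    def kin(self) -> float:
        return kin_from_baseline(self.r0, self.kout)


@dataclass(frozen=True)
class IL10Parameters:
    """IL-10 pathway: baseline turnover plus a disease-state production term.

    After the ConA challenge an additional zero-order production
    ``kin_dis`` (ng·L⁻¹·h⁻¹) switches on, modulated by
    ``F = 1 + T1c·s − C_IFN·i_ifn`` (precursor stimulation, linear IFN-γ
    inhibition on absolute IFN-γ concentration).
    """

    s: float
    kout: float
    kin_dis: float
    i_ifn: float
    r0: float

    def __post_init__(self):
        _require_positive(self, "s", "kout", "kin_dis", "i_ifn", "r0")

    @property
    def kin(self) -> float:
        return kin_from_baseline(self.r0, self.kout)


@dataclass(frozen=True)
class DiseaseParameters:
    """ALT/AST turnover driven by TNF-α and IFN-γ excess over baseline.

    ALT stimulation applies power exponents ``alpha`` (TNF-α) and ``beta``
    (IFN-γ), both fixed at 1.5 and never estimated; AST stimulation is linear.
    Baselines ``r0_alt``/``r0_ast`` are in U·L⁻¹.
    """

    s_alt_tnf: float
    s_alt_ifn: float
    kout_alt: float
    s_ast_tnf: float
    s_ast_ifn: float
    kout_ast: float
    r0_alt: float
    r0_ast: float
    alpha: float = 1.5
    beta: float = 1.5

    def __post_init__(self):
        _require_positive(
            self, "s_alt_tnf", "s_alt_ifn", "kout_alt",
            "s_ast_tnf", "s_ast_ifn", "kout_ast", "r0_alt", "r0_ast",
            "alpha", "beta",
        )

    @property
    def kin_alt(self) -> float:
        return kin_from_baseline(self.r0_alt, self.kout_alt)

    @property
    def kin_ast(self) -> float:
        return kin_from_baseline(self.r0_ast, self.kout_ast)


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter vector of the PK/PD/disease-progression model."""

    pk: PKParameters
    tau: float
    tnf: CytokinePathwayParameters
    ifn: CytokinePathwayParameters
    il6: CytokinePathwayParameters
    il10: IL10Parameters
    disease: DiseaseParameters
    cona_time: float = 0.5

    def __post_init__(self):
        _require_positive(self, "tau", "cona_time")
        expected = {"tnf": ("TNFa", 1), "ifn": ("IFNg", 7), "il6": ("IL6", 6)}
        for attr, (name, n) in expected.items():
            pathway = getattr(self, attr)
            if pathway.n_transit != n:
                raise DomainError(
                    f"{name} pathway must have {n} transit compartments, "
                    f"got {pathway.n_transit}"
                )

    def with_values(self, values: dict[str, float]) -> "ModelParameters":
        """Return a copy with named scalar parameters replaced.

        Names follow the canonical flat naming used across the package
        (``Vd_F``, ``ka``, ``ke``, ``tau``, ``kout_TNFa``, ``IC50_IFNg``,
        ``S_IL6``, ``kin_IL10_dis``, ``I_IL10_IFNg``, ``S_ALT_TNFa``,
        ``kout_AST`` ...).
        """
        flat = self.to_dict()
        unknown = set(values) - set(flat)
        if unknown:
            raise SchemaError(f"unknown parameter name(s): {sorted(unknown)}")
        flat.update(values)
        return ModelParameters.from_dict(flat)

    def to_dict(self) -> dict[str, float]:
        """Flatten to the canonical name → value mapping (kin values excluded)."""
        return {
            "Vd_F": self.pk.vd_f, "ka": self.pk.ka, "ke": self.pk.ke,
            "tau": self.tau,
            "Imax_TNFa": self.tnf.imax, "IC50_TNFa": self.tnf.ic50,
            "S_TNFa": self.tnf.s, "kout_TNFa": self.tnf.kout, "R0_TNFa": self.tnf.r0,
            "Imax_IFNg": self.ifn.imax, "IC50_IFNg": self.ifn.ic50,
            "S_IFNg": self.ifn.s, "kout_IFNg": self.ifn.kout, "R0_IFNg": self.ifn.r0,
            "Imax_IL6": self.il6.imax, "IC50_IL6": self.il6.ic50,
            "S_IL6": self.il6.s, "kout_IL6": self.il6.kout, "R0_IL6": self.il6.r0,
            "S_IL10": self.il10.s, "kout_IL10": self.il10.kout,
            "kin_IL10_dis": self.il10.kin_dis, "I_IL10_IFNg": self.il10.i_ifn,
            "R0_IL10": self.il10.r0,
            "S_ALT_TNFa": self.disease.s_alt_tnf, "S_ALT_IFNg": self.disease.s_alt_ifn,
            "kout_ALT": self.disease.kout_alt, "R0_ALT": self.disease.r0_alt,
            "S_AST_TNFa": self.disease.s_ast_tnf, "S_AST_IFNg": self.disease.s_ast_ifn,
            "kout_AST": self.disease.kout_ast, "R0_AST": self.disease.r0_ast,
            "alpha": self.disease.alpha, "beta": self.disease.beta,
            "cona_time": self.cona_time,
        }

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParameters":
        """Build from the canonical flat mapping produced by :meth:`to_dict`."""
        def need(key):
            if key not in d:
                raise SchemaError(f"missing required parameter {key!r}")
            return float(d[key])

        return cls(
            pk=PKParameters(vd_f=need("Vd_F"), ka=need("ka"), ke=need("ke")),
            tau=need("tau"),
            tnf=CytokinePathwayParameters(
                name="TNFa", n_transit=1, ic50=need("IC50_TNFa"), s=need("S_TNFa"),
                kout=need("kout_TNFa"), r0=need("R0_TNFa"),
                imax=float(d.get("Imax_TNFa", 1.0)),
            ),
            ifn=CytokinePathwayParameters(
                name="IFNg", n_transit=7, ic50=need("IC50_IFNg"), s=need("S_IFNg"),
                kout=need("kout_IFNg"), r0=need("R0_IFNg"),
                imax=float(d.get("Imax_IFNg", 1.0)),
            ),
            il6=CytokinePathwayParameters(
                name="IL6", n_transit=6, ic50=need("IC50_IL6"), s=need("S_IL6"),
                kout=need("kout_IL6"), r0=need("R0_IL6"),
                imax=float(d.get("Imax_IL6", 1.0)),
            ),
            il10=IL10Parameters(
                s=need("S_IL10"), kout=need("kout_IL10"), kin_dis=need("kin_IL10_dis"),
                i_ifn=need("I_IL10_IFNg"), r0=need("R0_IL10"),
            ),
            disease=DiseaseParameters(
                s_alt_tnf=need("S_ALT_TNFa"), s_alt_ifn=need("S_ALT_IFNg"),
                kout_alt=need("kout_ALT"), r0_alt=need("R0_ALT"),
                s_ast_tnf=need("S_AST_TNFa"), s_ast_ifn=need("S_AST_IFNg"),
                kout_ast=need("kout_AST"), r0_ast=need("R0_AST"),
                alpha=float(d.get("alpha", 1.5)), beta=float(d.get("beta", 1.5)),
            ),
            cona_time=float(d.get("cona_time", 0.5)),
        )


# ---------------------------------------------------------------------------
# State layout
# ---------------------------------------------------------------------------

STATE_NAMES: tuple[str, ...] = (
    "A_depot", "X_central",
    "T1",
    "T1a",
    "T1b", "T2b", "T3b", "T4b", "T5b", "T6b", "T7b",
    "T1c",
    "T1d", "T2d", "T3d", "T4d", "T5d", "T6d",
    "C_TNFa", "C_IFNg", "C_IL6", "C_IL10",
    "A_ALT", "A_AST",
)
STATE_INDEX: dict[str, int] = {name: i for i, name in enumerate(STATE_NAMES)}
N_STATES = len(STATE_NAMES)

# observable analyte name -> state index (drug handled separately: C = X/Vd_F)
OBSERVABLES: tuple[str, ...] = ("GRMS55", "TNFa", "IFNg", "IL6", "IL10", "ALT", "AST")
_ANALYTE_STATE = {
    "TNFa": STATE_INDEX["C_TNFa"],
    "IFNg": STATE_INDEX["C_IFNg"],
    "IL6": STATE_INDEX["C_IL6"],
    "IL10": STATE_INDEX["C_IL10"],
    "ALT": STATE_INDEX["A_ALT"],
    "AST": STATE_INDEX["A_AST"],
}


def observable_index(analyte: str) -> int | None:
    """State index of a biomarker analyte; ``None`` for the drug (derived)."""
    if analyte == "GRMS55":
        return None
    try:
        return _ANALYTE_STATE[analyte]
    except KeyError:
        raise SchemaError(f"unknown analyte {analyte!r}; expected one of {OBSERVABLES}") from None


# ---------------------------------------------------------------------------
# Algebraic building blocks
# ---------------------------------------------------------------------------

def inhibition_fraction(c_drug: float, ic50: float, imax: float = 1.0) -> float:
    """Fractional inhibition ``imax * C / (IC50 + C)``.

    Monotonically nondecreasing in ``c_drug``; tends to ``imax`` as C → ∞.
    """
    if not (ic50 > 0):
        raise DomainError(f"IC50 must be > 0, got {ic50!r}")
    if c_drug < 0:
        raise DomainError(f"drug concentration must be >= 0, got {c_drug!r}")
    if not (0.0 <= imax <= 1.0):
        raise DomainError(f"imax must lie in [0, 1], got {imax!r}")
    return imax * c_drug / (ic50 + c_drug)


def kin_from_baseline(r0: float, kout: float) -> float:
    """Zero-order production rate ``kin = R0 * kout`` (baseline constraint).

    Guarantees the unperturbed turnover ODE ``dC/dt = kin − kout·C`` has
    steady state exactly ``R0``.
    """
    if not (kout > 0):
        raise DomainError(f"kout must be > 0, got {kout!r}")
    if r0 < 0:
        raise DomainError(f"R0 must be >= 0, got {r0!r}")
    return r0 * kout


def pk_concentration(t, dose: float, pk: PKParameters):
    """Closed-form serum drug concentration (Bateman function).

    ``C(t) = (dose/Vd_F) · ka/(ka−ke) · (e^{−ke t} − e^{−ka t})``, with the
    ``t·e^{−kt}`` limiting form when ka ≈ ke.  Accepts scalar or array ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be >= 0")
    if dose < 0:
        raise DomainError(f"dose must be >= 0, got {dose!r}")
    ka, ke, vd = pk.ka, pk.ke, pk.vd_f
    if math.isclose(ka, ke, rel_tol=1e-12):
        c = (dose / vd) * ka * t * np.exp(-ka * t)
    else:
        c = (dose / vd) * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))
    return c if c.ndim else float(c)


# ---------------------------------------------------------------------------
# Full right-hand side
# ---------------------------------------------------------------------------

_I_DEPOT = STATE_INDEX["A_depot"]
_I_X = STATE_INDEX["X_central"]
_I_T1 = STATE_INDEX["T1"]
_I_T1A = STATE_INDEX["T1a"]
_I_B0 = STATE_INDEX["T1b"]
_I_T1C = STATE_INDEX["T1c"]
_I_D0 = STATE_INDEX["T1d"]
_I_TNF = STATE_INDEX["C_TNFa"]
_I_IFN = STATE_INDEX["C_IFNg"]
_I_IL6 = STATE_INDEX["C_IL6"]
_I_IL10 = STATE_INDEX["C_IL10"]
_I_ALT = STATE_INDEX["A_ALT"]
_I_AST = STATE_INDEX["A_AST"]


def full_rhs(t: float, state, params: ModelParameters, drug_present: bool = True,
             cona_given: bool = True) -> np.ndarray:
    """Time derivative of the full 24-dimensional state.

    Implements the printed system verbatim, including the dimensional
    asymmetry of the pathway inputs: the shared precursor T1 feeds the first
    pathway compartments *without* a 1/τ factor, while all downstream chain
    transfers (and the IL-10 precursor) carry 1/τ.  The IL-10 disease
    production switches on at ``t >= cona_time``; its modulating function
    ``F_IL10`` may go negative (that produces the observed IL-10 dip; the
    switch fires only when ``cona_given`` is true), but the
    total IL-10 production rate is floored at 0.  The ALT/AST driving excesses
    ``C − R0`` are clamped at 0 before the power/linear stimulation terms so
    transient solver undershoot cannot produce non-real powers.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (N_STATES,):
        raise DomainError(f"state must have length {N_STATES}, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        bad = int(np.flatnonzero(~np.isfinite(y))[0])
        raise IntegrationError(
            f"non-finite state entry at index {bad} ({STATE_NAMES[bad]}) at t={t}"
        )

    tau = params.tau
    inv_tau = 1.0 / tau
    dy = np.zeros(N_STATES)

    # --- PK ---
    a, x = y[_I_DEPOT], y[_I_X]
    dy[_I_DEPOT] = -params.pk.ka * a
    dy[_I_X] = params.pk.ka * a - params.pk.ke * x
    c_drug = (x / params.pk.vd_f) if drug_present else 0.0
    if c_drug < 0.0:
        c_drug = 0.0  # guard transient solver undershoot

    # --- shared precursor (switched on at the ConA challenge) ---
    t1 = y[_I_T1]
    dy[_I_T1] = -t1 * inv_tau if t >= params.cona_time else 0.0

    # --- TNF-α pathway (single transit compartment) ---
    t1a = y[_I_T1A]
    dy[_I_T1A] = t1 * (1.0 - inhibition_fraction(c_drug, params.tnf.ic50, params.tnf.imax)) \
        - t1a * inv_tau
    c_tnf = y[_I_TNF]
    dy[_I_TNF] = (1.0 + t1a * params.tnf.s) * params.tnf.kin - params.tnf.kout * c_tnf

    # --- IFN-γ pathway (chain of seven) ---
    dy[_I_B0] = t1 * (1.0 - inhibition_fraction(c_drug, params.ifn.ic50, params.ifn.imax)) \
        - y[_I_B0] * inv_tau
    for n in range(6):
        dy[_I_B0 + 1 + n] = (y[_I_B0 + n] - y[_I_B0 + 1 + n]) * inv_tau
    c_ifn = y[_I_IFN]
    dy[_I_IFN] = (1.0 + y[_I_B0 + 6] * params.ifn.s) * params.ifn.kin \
        - params.ifn.kout * c_ifn

    # --- IL-6 pathway (chain of six) ---
    dy[_I_D0] = t1 * (1.0 - inhibition_fraction(c_drug, params.il6.ic50, params.il6.imax)) \
        - y[_I_D0] * inv_tau
    for n in range(5):
        dy[_I_D0 + 1 + n] = (y[_I_D0 + n] - y[_I_D0 + 1 + n]) * inv_tau
    dy[_I_IL6] = (1.0 + y[_I_D0 + 5] * params.il6.s) * params.il6.kin \
        - params.il6.kout * y[_I_IL6]

    # --- IL-10 pathway ---
    t1c = y[_I_T1C]
    dy[_I_T1C] = (t1 - t1c) * inv_tau
    if cona_given and t >= params.cona_time:
        f_il10 = 1.0 + t1c * params.il10.s - c_ifn * params.il10.i_ifn
        production = params.il10.kin + f_il10 * params.il10.kin_dis
        if production < 0.0:
            production = 0.0
    else:
        production = params.il10.kin
    dy[_I_IL10] = production - params.il10.kout * y[_I_IL10]

    # --- disease progression (ALT/AST turnover) ---
    dis = params.disease
    ex_tnf = c_tnf - params.tnf.r0
    ex_ifn = c_ifn - params.ifn.r0
    if ex_tnf < 0.0:
        ex_tnf = 0.0
    if ex_ifn < 0.0:
        ex_ifn = 0.0
    f_alt = (1.0 + ex_tnf ** dis.alpha * dis.s_alt_tnf) \
        * (1.0 + ex_ifn ** dis.beta * dis.s_alt_ifn)
    f_ast = (1.0 + ex_tnf * dis.s_ast_tnf) * (1.0 + ex_ifn * dis.s_ast_ifn)
    dy[_I_ALT] = f_alt * dis.kin_alt - dis.kout_alt * y[_I_ALT]
    dy[_I_AST] = f_ast * dis.kin_ast - dis.kout_ast * y[_I_AST]

    return dy


def initial_state(params: ModelParameters, dose: float = 0.0) -> np.ndarray:
    """State vector at t = 0: dose in the depot, biomarkers at baseline."""
    if dose < 0:
        raise DomainError(f"dose must be >= 0, got {dose!r}")
    y0 = np.zeros(N_STATES)
    y0[_I_DEPOT] = dose
    y0[_I_TNF] = params.tnf.r0
    y0[_I_IFN] = params.ifn.r0
    y0[_I_IL6] = params.il6.r0
    y0[_I_IL10] = params.il10.r0
    y0[_I_ALT] = params.disease.r0_alt
    y0[_I_AST] = params.disease.r0_ast
    return y0
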