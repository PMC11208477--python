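"""Mass-action kinetic model of the photosynthetic electron transport chain.

The model tracks electrons from the oxygen-evolving complex (OEC)
through Photosystem II (PSII), the plastoquinone (PQ) pool, the
cytochrome b6/f complex, plastocyanin (Pc), Photosystem I (PSI) and
ferredoxin (Fd) to ferredoxin-NADP+ oxidoreductase (FNR), including the
cyclic routes from reduced Fd back to the b6/f complex and the PQ pool.

State space (43 variables)
--------------------------
Complexes are factorised into joint redox microstates, mobile carriers
into redox fractions:

* PSII: (P680 in {red, ox+}) x (Q_A in {ox, red}) x (Q_B in {ox,
  semi-reduced, doubly reduced}) -> 12 states summing to 1;
* OEC: S0..S3 -> 4 states summing to 1;
* PQ pool: PQ, PQ-, PQH2 -> 3 states summing to ``pq_total``;
* cyt b6/f: (haem f in {ox, red}) x (b_L in {ox, red}) x (b_H in {ox,
  singly red, doubly red}) -> 12 states summing to 1;
* Pc: reduced/oxidised -> 2 states summing to ``pc_total``;
* PSI: (P700 in {red, ox+}) x (F_B in {ox, red}) -> 4 states summing
  to 1;
* Fd: oxidised/reduced -> 2 states summing to ``fd_total``;
* FNR: inactive, active oxidised, singly and doubly reduced -> 4
  states summing to ``fnr_total``.

This factorisation (12+4+3+12+2+4+2+4 = 43) is a documented
*reconstruction*: it reproduces the published variable count and every
tabulated reaction, but the original model's exact state decomposition
is not printed anywhere, so microstate-level details (and hence exact
curve shapes) can differ.

Kinetics
--------
Intra-complex electron transfers are first order in the complex
microstate.  Transfers between a complex and a mobile pool are second
order, with the pool fraction normalised by the pool total so that all
rate constants keep units of 1/s:  flux = k * [complex state] *
([pool state] / pool_total).  The OEC <-> P680+ coupling is treated the
same way at pool level, with the flux distributed over P680+ substates
in proportion to their population.

Photochemistry and light
------------------------
The photochemical rate constants (charge separation and recombination
in both photosystems: k1f, k1b, k15f, k15b) scale linearly with photon
flux density relative to the reference PFD of 3255 photons/(m^2 s); the
tabulated values apply at the reference ("intense") intensity and drop
tenfold at PFD 325.5 ("low").

Fluorescence observable
-----------------------
F = [phi_open * (Q_A-oxidised PSII fraction) + phi_closed *
(Q_A-reduced fraction)] * (1 - gamma_PQ * PQ_ox / PQ_total): reduced
Q_A closes centres and raises yield; oxidised PQ quenches.  The yield
weights are a documented reconstruction (defaults phi_open = 1,
phi_closed = 5, gamma_PQ = 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "RateConstantSet",
    "PoolConfig",
    "InitialStateConfig",
    "QuenchConfig",
    "LightRegime",
    "Reaction",
    "ReactionNetwork",
    "SimulationResult",
    "OJIPFeatures",
    "FORWARD_NAMES",
    "BACKWARD_NAMES",
    "N_STATE",
    "STATE_NAMES",
    "build_network",
    "rhs",
    "rhs_brute_force",
    "initial_state",
    "pool_slices",
    "pool_totals_vector",
    "fluorescence",
    "simulate_fi",
    "extract_ojip_features",
    "default_time_grid",
    "INTENSE_PFD",
    "LOW_PFD",
]

INTENSE_PFD = 3255.0
LOW_PFD = 325.5

#: Screenable rate constants (18 forward, 14 backward), in table order.
FORWARD_NAMES = (
    "k1f", "k2", "k3", "k4", "k5", "k6f", "k7f", "k8f", "k9f", "k10f",
    "k11f", "k12f", "k13f", "k14f", "k15f", "k16f", "k17f", "k18f",
)
BACKWARD_NAMES = (
    "k1b", "k6b", "k7b", "k8b", "k9b", "k10b", "k11b", "k12b", "k13b",
    "k14b", "k15b", "k16b", "k17b", "k18b",
)

_DEFAULT_RATES = {
    "k1f": 2000.0, "k2": 20000.0, "k3": 10000.0, "k4": 3330.0, "k5": 1000.0,
    "k6f": 3500.0, "k7f": 1750.0, "k8f": 250.0, "k9f": 100.0, "k10f": 2300.0,
    "k11f": 100.0, "k12f": 100.0, "k13f": 100.0, "k14f": 1.0, "k15f": 2000.0,
    "k16f": 200.0, "k17f": 200.0, "k18f": 5.0,
    "k1b": 5000.0, "k6b": 175.0, "k7b": 35.0, "k8b": 250.0, "k9b": 10.0,
    "k10b": 7.0, "k11b": 10.0, "k12b": 10.0, "k13b": 100.0, "k14b": 1.0,
    "k15b": 10000.0, "k16b": 10.0, "k17b": 10.0, "k18b": 5.0,
}

#: Rate constants proportional to photon flux density.
_LIGHT_SCALED = ("k1f", "k1b", "k15f", "k15b")


@dataclass(frozen=True)
class RateConstantSet:
    """The 32 screenable rate constants plus two optional auxiliaries.

    ``fnr_activation`` (1/s, first-order inactive -> active FNR
    conversion) and ``fnr_sink`` (1/s, regeneration of oxidised FNR
    from the doubly reduced form, a terminal electron sink) both
    default to 0; by default the FNR pool starts already active.
    """

    values: dict = field(default_factory=dict)
    fnr_activation: float = 0.0
    fnr_sink: float = 0.0

    def __post_init__(self) -> None:
        merged = dict(_DEFAULT_RATES)
        for key, val in self.values.items():
            if key not in _DEFAULT_RATES:
                raise KeyError(f"unknown rate constant {key!r}")
            if val < 0:
                raise ValueError(f"rate constant {key} must be >= 0, got {val}")
            merged[key] = float(val)
        object.__setattr__(self, "values", merged)
        if self.fnr_activation < 0 or self.fnr_sink < 0:
            raise ValueError("auxiliary rates must be >= 0")

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def with_values(self, **overrides: float) -> "RateConstantSet":
        merged = dict(self.values)
        merged.update(overrides)
        return RateConstantSet(
            merged, fnr_activation=self.fnr_activation, fnr_sink=self.fnr_sink
        )

    def at_light(self, light: "LightRegime") -> "RateConstantSet":
        """Rate constants with photochemical entries scaled to the PFD."""
        factor = light.pfd / INTENSE_PFD
        scaled = {k: self.values[k] * factor for k in _LIGHT_SCALED}
        return self.with_values(**scaled)


@dataclass(frozen=True)
class LightRegime:
    """Illumination condition; ``pfd`` in photons m^-2 s^-1."""

    pfd: float = INTENSE_PFD

    def __post_init__(self) -> None:
        if self.pfd < 0:
            raise ValueError("pfd must be >= 0")

    @classmethod
    def intense(cls) -> "LightRegime":
        return cls(INTENSE_PFD)

    @classmethod
    def low(cls) -> "LightRegime":
        return cls(LOW_PFD)


@dataclass(frozen=True)
class PoolConfig:
    """Pool sizes as multiples of PSII (typical thylakoid stoichiometries)."""

    pq_total: float = 6.0
    pc_total: float = 2.0
    fd_total: float = 2.0
    fnr_total: float = 1.0

    def __post_init__(self) -> None:
        for name in ("pq_total", "pc_total", "fd_total", "fnr_total"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class InitialStateConfig:
    """Dark-adapted initial redox splits.

    Q_A starts fully oxidised (the definition of the O level); the
    S-state and Q_B/Q_B- splits follow common dark-adaptation practice
    and are configurable.  ``fnr_active`` controls whether the FNR pool
    starts in the active oxidised form or inactive.
    """

    s1_fraction: float = 0.75  # remainder is S0
    qb_semi_fraction: float = 0.5  # Q_B- share of PSII; remainder Q_B
    fnr_active: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.s1_fraction <= 1:
            raise ValueError("s1_fraction must lie in [0, 1]")
        if not 0 <= self.qb_semi_fraction <= 1:
            raise ValueError("qb_semi_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class QuenchConfig:
    """Fluorescence yield weights and quenching strengths."""

    phi_open: float = 1.0
    phi_closed: float = 5.0
    gamma_pq: float = 0.3
    gamma_p680_ox: float = 0.0  # optional P680+ quenching, default off

    def __post_init__(self) -> None:
        if min(self.phi_open, self.phi_closed) < 0:
            raise ValueError("yield weights must be >= 0")
        if not 0 <= self.gamma_pq < 1 or not 0 <= self.gamma_p680_ox < 1:
            raise ValueError("quenching factors must lie in [0, 1)")


# ----------------------------------------------------------------------
# State indexing
# ----------------------------------------------------------------------

def _psii(p680: int, qa: int, qb: int) -> int:
    return p680 * 6 + qa * 3 + qb


_OFF_PSII = 0
_OFF_OEC = 12
_OFF_PQ = 16  # PQ, PQ-, PQH2
_OFF_CYT = 19


def _cyt(f: int, bl: int, bh: int) -> int:
    return _OFF_CYT + f * 6 + bl * 3 + bh


_OFF_PC = 31  # Pc_red, Pc_ox
_OFF_PSI = 33


def _psi(p700: int, fb: int) -> int:
    return _OFF_PSI + p700 * 2 + fb


_OFF_FD = 37  # Fd_ox, Fd_red
_OFF_FNR = 39  # inactive, active_ox, FNR-, FNR2-
N_STATE = 43

STATE_NAMES = tuple(
    [
        f"PSII_P680{'p' if p else ''}_QA{'m' if a else ''}_QB{['','m','2m'][b]}"
        for p in (0, 1) for a in (0, 1) for b in (0, 1, 2)
    ]
    + [f"S{i}" for i in range(4)]
    + ["PQ", "PQm", "PQH2"]
    + [
        f"CYT_f{'m' if f else ''}_bL{'m' if bl else ''}_bH{['','m','2m'][bh]}"
        for f in (0, 1) for bl in (0, 1) for bh in (0, 1, 2)
    ]
    + ["Pc_red", "Pc_ox"]
    + [f"PSI_P700{'p' if p else ''}_FB{'m' if fb else ''}" for p in (0, 1) for fb in (0, 1)]
    + ["Fd_ox", "Fd_red"]
    + ["FNR_inactive", "FNR_act", "FNRm", "FNR2m"]
)


def pool_slices() -> dict[str, slice]:
    """Index ranges of the conserved sub-pools."""
    return {
        "PSII": slice(0, 12),
        "OEC": slice(12, 16),
        "PQ": slice(16, 19),
        "CYT": slice(19, 31),
        "Pc": slice(31, 33),
        "PSI": slice(33, 37),
        "Fd": slice(37, 39),
        "FNR": slice(39, 43),
    }


def pool_totals_vector(pools: PoolConfig) -> dict[str, float]:
    return {
        "PSII": 1.0,
        "OEC": 1.0,
        "PQ": pools.pq_total,
        "CYT": 1.0,
        "Pc": pools.pc_total,
        "PSI": 1.0,
        "Fd": pools.fd_total,
        "FNR": pools.fnr_total,
    }


# ----------------------------------------------------------------------
# Reaction network
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action transition.

    ``flux = k * x[substrate] * (x[partner] / partner_total)`` with the
    partner factor equal to 1 for first-order (intra-complex) steps.
    ``stoich`` maps state index -> net coefficient.
    """

    name: str
    rate_name: str
    substrate: int
    partner: int  # -1 for first-order reactions
    partner_total: float
    stoich: tuple[tuple[int, float], ...]


@dataclass
class ReactionNetwork:
    """Reaction list plus the dense stoichiometry matrix derived from it."""

    reactions: list[Reaction]
    rates: RateConstantSet
    pools: PoolConfig

    def __post_init__(self) -> None:
        n_rx = len(self.reactions)
        self.stoich_matrix = np.zeros((N_STATE, n_rx))
        self._k = np.empty(n_rx)
        self._sub = np.empty(n_rx, dtype=int)
        self._par = np.empty(n_rx, dtype=int)
        self._par_tot = np.empty(n_rx)
        for j, rx in enumerate(self.reactions):
            for idx, coef in rx.stoich:
                self.stoich_matrix[idx, j] += coef
            self._k[j] = self._rate_value(rx.rate_name)
            self._sub[j] = rx.substrate
            self._par[j] = rx.partner
            self._par_tot[j] = rx.partner_total

    def _rate_value(self, rate_name: str) -> float:
        if rate_name == "fnr_activation":
            return self.rates.fnr_activation
        if rate_name == "fnr_sink":
            return self.rates.fnr_sink
        return self.rates[rate_name]

    def fluxes(self, x: np.ndarray) -> np.ndarray:
        partner = np.where(
            self._par >= 0, x[np.clip(self._par, 0, None)] / self._par_tot, 1.0
        )
        return self._k * x[self._sub] * partner


def _transfer(sub_from: int, sub_to: int) -> tuple[tuple[int, float], ...]:
    return ((sub_from, -1.0), (sub_to, 1.0))


def build_network(
    rates: RateConstantSet,
    pools: PoolConfig | None = None,
    *,
    k8_both_qa_states: bool = False,
) -> ReactionNetwork:
    """Instantiate every tabulated reaction over the microstate space.

    By default the Q_B-site plastoquinone exchange (k8f/k8b) runs only
    in open (Q_A-oxidised) centres, as the reaction is written
    (Q_A Q_B(2-) + PQ -> Q_A Q_B + PQH2).  Set ``k8_both_qa_states``
    to allow it for both Q_A redox states (exchange chemistry at the
    Q_B pocket arguably does not involve Q_A); gating it on open
    centres is also what produces the characteristic I plateau here.
    """
    pools = pools or PoolConfig()
    pq, pqm, pqh2 = _OFF_PQ, _OFF_PQ + 1, _OFF_PQ + 2
    pc_red, pc_ox = _OFF_PC, _OFF_PC + 1
    fd_ox, fd_red = _OFF_FD, _OFF_FD + 1
    fnr_in, fnr_act, fnr_m, fnr_2m = range(_OFF_FNR, _OFF_FNR + 4)
    rx: list[Reaction] = []

    def add(name, rate, sub, stoich, partner=-1, partner_total=1.0):
        rx.append(Reaction(name, rate, sub, partner, partner_total, tuple(stoich)))

    # --- PSII photochemistry: P680 QA -> P680+ QA-  (and recombination)
    for qb in range(3):
        add(f"k1f_qb{qb}", "k1f", _psii(0, 0, qb),
            _transfer(_psii(0, 0, qb), _psii(1, 1, qb)))
        add(f"k1b_qb{qb}", "k1b", _psii(1, 1, qb),
            _transfer(_psii(1, 1, qb), _psii(0, 0, qb)))

    # --- OEC S-state advance: Si P680+ -> S(i+1) P680 (pool-level coupling)
    s_rates = ("k2", "k3", "k4", "k5")
    for i, rate in enumerate(s_rates):
        s_from = _OFF_OEC + i
        s_to = _OFF_OEC + (i + 1) % 4
        for qa in range(2):
            for qb in range(3):
                add(
                    f"{rate}_qa{qa}_qb{qb}", rate, _psii(1, qa, qb),
                    _transfer(_psii(1, qa, qb), _psii(0, qa, qb))
                    + _transfer(s_from, s_to),
                    partner=s_from, partner_total=1.0,
                )

    # --- two-electron gate: QA- QB -> QA QB-, QA- QB- -> QA QB2-
    for p in range(2):
        add(f"k6f_p{p}", "k6f", _psii(p, 1, 0), _transfer(_psii(p, 1, 0), _psii(p, 0, 1)))
        add(f"k6b_p{p}", "k6b", _psii(p, 0, 1), _transfer(_psii(p, 0, 1), _psii(p, 1, 0)))
        add(f"k7f_p{p}", "k7f", _psii(p, 1, 1), _transfer(_psii(p, 1, 1), _psii(p, 0, 2)))
        add(f"k7b_p{p}", "k7b", _psii(p, 0, 2), _transfer(_psii(p, 0, 2), _psii(p, 1, 1)))

    # --- QB-site exchange with the PQ pool (k8): QA QB2- + PQ -> QA QB + PQH2
    qa_states_k8 = range(2) if k8_both_qa_states else (0,)
    for p in range(2):
        for qa in qa_states_k8:
            add(
                f"k8f_p{p}_qa{qa}", "k8f", _psii(p, qa, 2),
                _transfer(_psii(p, qa, 2), _psii(p, qa, 0))
                + _transfer(pq, pqh2),
                partner=pq, partner_total=pools.pq_total,
            )
            add(
                f"k8b_p{p}_qa{qa}", "k8b", _psii(p, qa, 0),
                _transfer(_psii(p, qa, 0), _psii(p, qa, 2))
                + _transfer(pqh2, pq),
                partner=pqh2, partner_total=pools.pq_total,
            )

    # --- PQH2 oxidation at the luminal (Qo) site: PQH2 + f bL -> PQ + f- bL-
    for bh in range(3):
        add(
            f"k9f_bh{bh}", "k9f", _cyt(0, 0, bh),
            _transfer(_cyt(0, 0, bh), _cyt(1, 1, bh)) + _transfer(pqh2, pq),
            partner=pqh2, partner_total=pools.pq_total,
        )
        add(
            f"k9b_bh{bh}", "k9b", _cyt(1, 1, bh),
            _transfer(_cyt(1, 1, bh), _cyt(0, 0, bh)) + _transfer(pq, pqh2),
            partner=pq, partner_total=pools.pq_total,
        )

    # --- bL -> bH transfer (both bH acceptor steps share k10f)
    for f in range(2):
        for bh in (0, 1):
            add(f"k10f_f{f}_bh{bh}", "k10f", _cyt(f, 1, bh),
                _transfer(_cyt(f, 1, bh), _cyt(f, 0, bh + 1)))
            add(f"k10b_f{f}_bh{bh}", "k10b", _cyt(f, 0, bh + 1),
                _transfer(_cyt(f, 0, bh + 1), _cyt(f, 1, bh)))

    # --- stromal (Qi) site: bH2- + PQ -> bH + PQH2
    for f in range(2):
        for bl in range(2):
            add(
                f"k11f_f{f}_bl{bl}", "k11f", _cyt(f, bl, 2),
                _transfer(_cyt(f, bl, 2), _cyt(f, bl, 0)) + _transfer(pq, pqh2),
                partner=pq, partner_total=pools.pq_total,
            )
            add(
                f"k11b_f{f}_bl{bl}", "k11b", _cyt(f, bl, 0),
                _transfer(_cyt(f, bl, 0), _cyt(f, bl, 2)) + _transfer(pqh2, pq),
                partner=pqh2, partner_total=pools.pq_total,
            )

    # --- haem f <-> plastocyanin: f- Pc+ -> f Pc
    for bl in range(2):
        for bh in range(3):
            add(
                f"k12f_bl{bl}_bh{bh}", "k12f", _cyt(1, bl, bh),
                _transfer(_cyt(1, bl, bh), _cyt(0, bl, bh))
                + _transfer(pc_ox, pc_red),
                partner=pc_ox, partner_total=pools.pc_total,
            )
            add(
                f"k12b_bl{bl}_bh{bh}", "k12b", _cyt(0, bl, bh),
                _transfer(_cyt(0, bl, bh), _cyt(1, bl, bh))
                + _transfer(pc_red, pc_ox),
                partner=pc_red, partner_total=pools.pc_total,
            )

    # --- cyclic route: bH + Fd- -> bH- + Fd (both bH acceptor steps)
    for f in range(2):
        for bl in range(2):
            for bh in (0, 1):
                add(
                    f"k13f_f{f}_bl{bl}_bh{bh}", "k13f", _cyt(f, bl, bh),
                    _transfer(_cyt(f, bl, bh), _cyt(f, bl, bh + 1))
                    + _transfer(fd_red, fd_ox),
                    partner=fd_red, partner_total=pools.fd_total,
                )
                add(
                    f"k13b_f{f}_bl{bl}_bh{bh}", "k13b", _cyt(f, bl, bh + 1),
                    _transfer(_cyt(f, bl, bh + 1), _cyt(f, bl, bh))
                    + _transfer(fd_ox, fd_red),
                    partner=fd_ox, partner_total=pools.fd_total,
                )

    # --- cyclic route: PQ + Fd- -> PQ- + Fd, PQ- + Fd- -> PQH2 + Fd
    for sub_from, sub_to, tag in ((pq, pqm, "1"), (pqm, pqh2, "2")):
        add(
            f"k14f_{tag}", "k14f", sub_from,
            _transfer(sub_from, sub_to) + _transfer(fd_red, fd_ox),
            partner=fd_red, partner_total=pools.fd_total,
        )
        add(
            f"k14b_{tag}", "k14b", sub_to,
            _transfer(sub_to, sub_from) + _transfer(fd_ox, fd_red),
            partner=fd_ox, partner_total=pools.fd_total,
        )

    # --- PSI photochemistry: P700 FB -> P700+ FB-  (and recombination)
    add("k15f", "k15f", _psi(0, 0), _transfer(_psi(0, 0), _psi(1, 1)))
    add("k15b", "k15b", _psi(1, 1), _transfer(_psi(1, 1), _psi(0, 0)))

    # --- Pc -> P700+: Pc + P700+ -> Pc+ + P700
    for fb in range(2):
        add(
            f"k16f_fb{fb}", "k16f", _psi(1, fb),
            _transfer(_psi(1, fb), _psi(0, fb)) + _transfer(pc_red, pc_ox),
            partner=pc_red, partner_total=pools.pc_total,
        )
        add(
            f"k16b_fb{fb}", "k16b", _psi(0, fb),
            _transfer(_psi(0, fb), _psi(1, fb)) + _transfer(pc_ox, pc_red),
            partner=pc_ox, partner_total=pools.pc_total,
        )

    # --- FB- -> Fd: FB- + Fd -> FB + Fd-
    for p700 in range(2):
        add(
            f"k17f_p{p700}", "k17f", _psi(p700, 1),
            _transfer(_psi(p700, 1), _psi(p700, 0)) + _transfer(fd_ox, fd_red),
            partner=fd_ox, partner_total=pools.fd_total,
        )
        add(
            f"k17b_p{p700}", "k17b", _psi(p700, 0),
            _transfer(_psi(p700, 0), _psi(p700, 1)) + _transfer(fd_red, fd_ox),
            partner=fd_red, partner_total=pools.fd_total,
        )

    # --- Fd- -> FNR (two sequential reductions of the active complex)
    for sub_from, sub_to, tag in ((fnr_act, fnr_m, "1"), (fnr_m, fnr_2m, "2")):
        add(
            f"k18f_{tag}", "k18f", sub_from,
            _transfer(sub_from, sub_to) + _transfer(fd_red, fd_ox),
            partner=fd_red, partner_total=pools.fd_total,
        )
        add(
            f"k18b_{tag}", "k18b", sub_to,
            _transfer(sub_to, sub_from) + _transfer(fd_ox, fd_red),
            partner=fd_ox, partner_total=pools.fd_total,
        )

    # --- optional auxiliaries (default rates 0)
    add("fnr_activation", "fnr_activation", fnr_in, _transfer(fnr_in, fnr_act))
    add("fnr_sink", "fnr_sink", fnr_2m, _transfer(fnr_2m, fnr_act))

    return ReactionNetwork(rx, rates, pools)


def rhs(network: ReactionNetwork, x: np.ndarray) -> np.ndarray:
    """Time derivative: stoichiometry matrix times flux vector."""
    return network.stoich_matrix @ network.fluxes(x)


def rhs_brute_force(network: ReactionNetwork, x: np.ndarray) -> np.ndarray:
    """Reference derivative accumulated reaction by reaction.

    Deliberately avoids the precomputed stoichiometry matrix and the
    vectorised flux evaluation so it can serve as an independent check
    of :func:`rhs`.
    """
    dx = np.zeros(N_STATE)
    for reaction in network.reactions:
        k = network._rate_value(reaction.rate_name)
        flux = k * x[reaction.substrate]
        if reaction.partner >= 0:
            flux *= x[reaction.partner] / reaction.partner_total
        for idx, coef in reaction.stoich:
            dx[idx] += coef * flux
    return dx


def initial_state(
    init: InitialStateConfig | None = None,
    pools: PoolConfig | None = None,
) -> np.ndarray:
    """Dark-adapted initial state.

    Q_A fully oxidised (O level definition); P680 and P700 reduced
    (neutral); the PQ pool and Fd fully oxidised; Pc reduced; cyt b6/f
    haems oxidised; S1:S0 and Q_B:Q_B- splits from ``init``.
    """
    init = init or InitialStateConfig()
    pools = pools or PoolConfig()
    x = np.zeros(N_STATE)
    # PSII: P680 reduced, QA oxidised, QB split between QB and QB-
    x[_psii(0, 0, 0)] = 1.0 - init.qb_semi_fraction
    x[_psii(0, 0, 1)] = init.qb_semi_fraction
    # OEC
    x[_OFF_OEC + 0] = 1.0 - init.s1_fraction
    x[_OFF_OEC + 1] = init.s1_fraction
    # PQ pool fully oxidised
    x[_OFF_PQ] = pools.pq_total
    # cyt b6/f fully oxidised
    x[_cyt(0, 0, 0)] = 1.0
    # Pc reduced
    x[_OFF_PC] = pools.pc_total
    # PSI: P700 reduced, FB oxidised
    x[_psi(0, 0)] = 1.0
    # Fd oxidised
    x[_OFF_FD] = pools.fd_total
    # FNR
    x[_OFF_FNR + (1 if init.fnr_active else 0)] = pools.fnr_total
    _check_pools(x, pools)
    return x


def _check_pools(x: np.ndarray, pools: PoolConfig, tol: float = 1e-9) -> None:
    totals = pool_totals_vector(pools)
    for name, sl in pool_slices().items():
        if abs(x[sl].sum() - totals[name]) > tol:
            raise ValueError(
                f"pool {name} sums to {x[sl].sum()}, expected {totals[name]}"
            )


def fluorescence(
    states: np.ndarray,
    quench: QuenchConfig | None = None,
    pools: PoolConfig | None = None,
) -> np.ndarray:
    """Fluorescence observable for state vector(s).

    ``states`` may be a single state (shape (43,)) or a trajectory
    (shape (43, n_time)).
    """
    quench = quench or QuenchConfig()
    pools = pools or PoolConfig()
    x = np.atleast_2d(states.T).T if states.ndim == 1 else states
    psii = x[pool_slices()["PSII"]]
    qa_red = psii.reshape(2, 2, 3, -1)[:, 1, :, :].sum(axis=(0, 1))
    qa_ox = psii.reshape(2, 2, 3, -1)[:, 0, :, :].sum(axis=(0, 1))
    p680_ox = psii.reshape(2, 2, 3, -1)[1].sum(axis=(0, 1))
    pq_ox = x[_OFF_PQ]
    f = (quench.phi_open * qa_ox + quench.phi_closed * qa_red) * (
        1.0 - quench.gamma_pq * pq_ox / pools.pq_total
    ) * (1.0 - quench.gamma_p680_ox * p680_ox)
    if np.any(f < 0):
        raise ValueError("fluorescence became negative; check quench config")
    return f[0] if states.ndim == 1 else f


def default_time_grid(
    t_min: float = 1e-5, t_max: float = 1.0, points_per_decade: int = 60
) -> np.ndarray:
    """Logarithmic output grid (the natural axis for O-J-I-P curves)."""
    n_dec = np.log10(t_max / t_min)
    return np.logspace(
        np.log10(t_min), np.log10(t_max), int(round(n_dec * points_per_decade)) + 1
    )


@dataclass
class SimulationResult:
    """Simulated species trajectories and the fluorescence observable."""

    time_grid: np.ndarray
    species: np.ndarray  # (43, n_time)
    fluorescence: np.ndarray
    pools: PoolConfig
    light: LightRegime


def simulate_fi(
    rates: RateConstantSet | None = None,
    light: LightRegime | None = None,
    *,
    pools: PoolConfig | None = None,
    init: InitialStateConfig | np.ndarray | None = None,
    quench: QuenchConfig | None = None,
    time_grid: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    k8_both_qa_states: bool = False,
) -> SimulationResult:
    """Simulate a fluorescence-induction transient.

    Integrates the 43-variable stiff system from the dark-adapted state
    under the given light regime and returns species and F(t) on a
    logarithmic time grid (default 60 points per decade over
    [1e-5, 1] s).
    """
    rates = rates or RateConstantSet()
    light = light or LightRegime.intense()
    pools = pools or PoolConfig()
    quench = quench or QuenchConfig()
    if time_grid is None:
        time_grid = default_time_grid()
    if np.any(np.diff(time_grid) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if isinstance(init, np.ndarray):
        x0 = init.copy()
        _check_pools(x0, pools)
    else:
        x0 = initial_state(init, pools)

    network = build_network(
        rates.at_light(light), pools, k8_both_qa_states=k8_both_qa_states
    )
    sm = network.stoich_matrix

    def f(_t: float, x: np.ndarray) -> np.ndarray:
        return sm @ network.fluxes(x)

    t0 = 0.0
    sol = solve_ivp(
        f,
        (t0, time_grid[-1]),
        x0,
        t_eval=time_grid,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed ({sol.message}) for rates "
            f"{ {n: network.rates[n] for n in FORWARD_NAMES + BACKWARD_NAMES} }"
        )
    species = sol.y
    if np.min(species) < -1e-6:
        raise RuntimeError(
            f"state went negative beyond tolerance: min={np.min(species)}"
        )
    return SimulationResult(
        time_grid=time_grid,
        species=species,
        fluorescence=fluorescence(species, quench, pools),
        pools=pools,
        light=light,
    )


# ----------------------------------------------------------------------
# O-J-I-P feature extraction
# ----------------------------------------------------------------------

@dataclass
class OJIPFeatures:
    """Detected landmark levels/times; undetected features are None."""

    f_o: float
    f_p: float
    t_p: float
    f_j: float | None = None
    t_j: float | None = None
    f_i: float | None = None
    t_i: float | None = None


def extract_ojip_features(
    time_grid: np.ndarray,
    f: np.ndarray,
    *,
    j_window: tuple[float, float] = (3e-4, 1e-2),
    i_window: tuple[float, float] = (1e-2, 1e-1),
    min_points_per_decade: int = 50,
) -> OJIPFeatures:
    """Locate the O, J, I and P landmarks of a fluorescence rise.

    F_P is the global maximum of F.  J and I are plateau/inflection
    points: local minima of the log-time slope dF/dlog10(t) inside the
    search windows (default (0.3, 10) ms for J and (10, 100) ms for I).
    A window with no interior slope minimum, or one whose slope never
    dips below the window-edge slopes, reports the feature as
    undetected rather than fabricating it.

    t_P is the argmax time when the maximum is interior (the curve
    declines afterwards).  On a curve that only saturates, the literal
    argmax sits wherever solver noise puts it on the terminal plateau,
    so t_P is instead placed at the dominant inflection of the final
    rise: the largest slope maximum after the last detected plateau
    (falling back to the whole curve, and to the final point when the
    slope keeps growing to the end).
    """
    t = np.asarray(time_grid, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    log_t = np.log10(t)
    density = (len(t) - 1) / (log_t[-1] - log_t[0])
    if density < min_points_per_decade:
        raise ValueError(
            f"grid too coarse for feature detection: {density:.0f} "
            f"points/decade < {min_points_per_decade}"
        )
    ip = int(np.argmax(f))
    features = OJIPFeatures(f_o=float(f[0]), f_p=float(f[ip]), t_p=float(t[ip]))
    slope = np.gradient(f, log_t)

    def interior_max(i: int) -> bool:
        return 0 < i < len(f) - 1 and f[i] > f[-1]

    def plateau(window: tuple[float, float]):
        mask = (t > window[0]) & (t < window[1])
        if mask.sum() < 5:
            return None
        idx = np.nonzero(mask)[0]
        s = slope[idx]
        # interior local minima of the log-slope: candidate plateaus
        local_min = np.nonzero((s[1:-1] < s[:-2]) & (s[1:-1] <= s[2:]))[0] + 1
        if len(local_min) == 0:
            return None
        # prominence: how far the slope rises again on both sides; guards
        # against solver ripple posing as an inflection
        span = float(s.max() - s.min())
        if span <= 0:
            return None
        best, best_prom = None, 0.0
        for i in local_min:
            rise = min(float(s[:i].max() - s[i]), float(s[i:].max() - s[i]))
            if rise > best_prom:
                best, best_prom = i, rise
        if best is None or best_prom < 0.02 * span:
            return None
        return idx[best]

    ij = plateau(j_window)
    if ij is not None:
        features.t_j = float(t[ij])
        features.f_j = float(f[ij])
    ii = plateau(i_window)
    if ii is not None and (ij is None or ii > ij):
        features.t_i = float(t[ii])
        features.f_i = float(f[ii])

    if not interior_max(ip):
        start = ii if ii is not None else (ij if ij is not None else 0)
        region = slice(start + 1, len(f) - 1)
        s = slope[region]
        local_max = np.nonzero(
            (s[1:-1] > s[:-2]) & (s[1:-1] >= s[2:])
        )[0]
        if len(local_max) > 0:
            best = local_max[np.argmax(s[local_max + 1])] + 1
            features.t_p = float(t[region][best])
            features.f_p = float(f[ip])  # level stays the global max
        # else: slope still growing at the end; keep t_p at the last point
    return features
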