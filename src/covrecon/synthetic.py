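"""Synthetic mass-action kinetic models with known ground truth.

The generators here stand in for curated kinetic models: random sparse
mass-action networks with inflow/outflow reactions, guaranteed to admit
a positive, Hurwitz-stable steady state.  From a model we obtain the
true Jacobian (analytically for mass action, cross-checkable by finite
differences), two-condition pairs via parameter perturbation, and
covariance data either exactly from the Lyapunov equation with
randomized diagonal fluctuation matrices, or empirically from
Euler–Maruyama simulation of the chemical Langevin-style SDE
dM = F(M) dt + sigma dW.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .lyapunov import CovarianceMatrix, FluctuationMatrix, Jacobian, solve_forward_lyapunov

__all__ = [
    "KineticReaction",
    "KineticModel",
    "ConditionPair",
    "NoiseSpec",
    "generate_mass_action_model",
    "remove_conserved_moieties",
    "steady_state_and_jacobian",
    "covariance_via_lyapunov",
    "covariance_via_sde",
    "make_condition_pair",
    "fixture_model",
    "FIXTURE_SIZES",
]


@dataclass
class KineticReaction:
    """Mass-action reaction: rate = k * prod substrates^coeff.

    Empty ``substrates`` encodes a zeroth-order inflow; empty
    ``products`` an outflow/degradation sink.
    """

    name: str
    substrates: dict[str, float]
    products: dict[str, float]
    rate_param: str


@dataclass
class KineticModel:
    species: list[str]
    reactions: list[KineticReaction]
    parameters: dict[str, float]
    # conservation bookkeeping filled by remove_conserved_moieties:
    # (removed species, {species: coeff} over the original species, total)
    conservations: list[tuple[str, dict[str, float], float]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.species)

    def _compiled(self):
        if not hasattr(self, "_cache"):
            idx = {s: i for i, s in enumerate(self.species)}
            nr = len(self.reactions)
            S = np.zeros((self.n, nr))
            E = np.zeros((self.n, nr))
            k = np.zeros(nr)
            for r, rx in enumerate(self.reactions):
                k[r] = self.parameters[rx.rate_param]
                for sp, c in rx.substrates.items():
                    if sp in idx:
                        S[idx[sp], r] -= c
                        E[idx[sp], r] += c
                for sp, c in rx.products.items():
                    if sp in idx:
                        S[idx[sp], r] += c
            self._cache = (S, E, k)
        return self._cache

    def invalidate(self) -> None:
        if hasattr(self, "_cache"):
            del self._cache

    def rates(self, M: np.ndarray) -> np.ndarray:
        S, E, k = self._compiled()
        Mc = np.clip(np.asarray(M, dtype=float), 0.0, None)
        return k * np.prod(Mc[:, None] ** E, axis=0)

    def f(self, M: np.ndarray) -> np.ndarray:
        """dM/dt = S v(M)."""
        S, E, k = self._compiled()
        return S @ self.rates(M)

    def stoichiometric_matrix(self) -> np.ndarray:
        return self._compiled()[0].copy()

    def analytic_jacobian(self, M: np.ndarray) -> np.ndarray:
        """Exact mass-action Jacobian: dv_r/dM_j = v_r * E_jr / M_j."""
        S, E, k = self._compiled()
        M = np.asarray(M, dtype=float)
        v = self.rates(M)
        with np.errstate(divide="ignore", invalid="ignore"):
            dv = v[None, :] * E / M[:, None]            # (species j, reaction r)
        dv = np.where(E > 0, np.nan_to_num(dv, nan=0.0, posinf=0.0), 0.0)
        return S @ dv.T

    def to_json(self, path) -> None:
        payload = {
            "species": self.species,
            "parameters": self.parameters,
            "reactions": [
                {"name": r.name, "substrates": r.substrates,
                 "products": r.products, "rate_param": r.rate_param}
                for r in self.reactions
            ],
            "conservations": [
                {"removed": s, "coeffs": w, "total": t} for s, w, t in self.conservations
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "KineticModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            species=list(payload["species"]),
            reactions=[KineticReaction(**r) for r in payload["reactions"]],
            parameters=dict(payload["parameters"]),
            conservations=[(c["removed"], dict(c["coeffs"]), float(c["total"]))
                           for c in payload.get("conservations", [])],
        )


@dataclass
class ConditionPair:
    model_h: KineticModel
    model_d: KineticModel
    perturbed: list[tuple[str, float]]


@dataclass
class NoiseSpec:
    """SDE sampling protocol for empirical covariance generation."""

    sde_sigma: float = 0.05
    n_samples: int = 1000
    dt: float = 0.01
    burn_in: int = 2000
    thin: int = 50
    eps_d: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.eps_d < 1):
            raise ValueError("eps_d must lie in [0, 1)")
        if self.sde_sigma < 0 or self.dt <= 0 or self.n_samples < 1 or self.burn_in < 0:
            raise ValueError("invalid noise specification")


def generate_mass_action_model(n_species: int, n_reactions: int, seed: int,
                               bimolecular_fraction: float = 0.0,
                               max_retries: int = 60) -> KineticModel:
    """Random sparse mass-action network with a positive stable steady state.

    The backbone is an open chain (inflow -> X0 -> ... -> X_{n-1} -> sink)
    which guarantees openness; extra uni- or bi-molecular conversions are
    added at random until ``n_reactions`` internal reactions exist, and
    every species additionally receives a first-order dilution/degradation
    sink so the Jacobian diagonal is strictly negative.  Candidates are
    rejected (and re-drawn) until the steady state is positive and the
    Jacobian Hurwitz-stable.
    """
    if n_reactions < n_species - 1:
        raise ValueError("need at least n_species - 1 reactions to connect the chain")
    master = np.random.default_rng(seed)
    for _ in range(max_retries):
        rng = np.random.default_rng(master.integers(2 ** 31))
        model = _draw_model(n_species, n_reactions, rng, bimolecular_fraction)
        try:
            M, J = steady_state_and_jacobian(model)
        except (ArithmeticError, ValueError):
            continue
        if np.all(M > 1e-8) and np.max(np.linalg.eigvals(J.values).real) < -1e-8:
            return model
    raise RuntimeError(f"no stable model found for seed {seed}; try a different seed")


def _draw_model(n: int, n_reactions: int, rng: np.random.Generator,
                bi_frac: float) -> KineticModel:
    species = [f"X{i}" for i in range(n)]
    params: dict[str, float] = {}
    reactions: list[KineticReaction] = []

    def add(name, subs, prods, k):
        pname = f"k_{name}"
        params[pname] = float(k)
        reactions.append(KineticReaction(name, subs, prods, pname))

    add("in", {}, {species[0]: 1.0}, 1.0)
    for i in range(n - 1):
        add(f"chain{i}", {species[i]: 1.0}, {species[i + 1]: 1.0}, rng.uniform(0.8, 1.5))
    for i in range(n):
        add(f"deg{i}", {species[i]: 1.0}, {}, rng.uniform(0.3, 0.8))
    n_extra = max(0, n_reactions - (n - 1))
    for e in range(n_extra):
        if rng.uniform() < bi_frac and n >= 3:
            a, b, c = rng.choice(n, size=3, replace=False)
            add(f"bi{e}", {species[a]: 1.0, species[b]: 1.0}, {species[c]: 1.0},
                rng.uniform(0.05, 0.2))
        else:
            a, b = rng.choice(n, size=2, replace=False)
            add(f"uni{e}", {species[a]: 1.0}, {species[b]: 1.0}, rng.uniform(0.1, 0.5))
    return KineticModel(species=species, reactions=reactions, parameters=params)


def remove_conserved_moieties(model: KineticModel) -> KineticModel:
    """Drop constant species and one dependent species per conservation law.

    Conservation relations are the left null space of the stoichiometric
    matrix.  For each independent relation the highest-index participating
    species is removed and its concentration re-expressed through the
    conserved total at the model's reference state (all-ones if no steady
    state is available yet).  Constant species (all-zero stoichiometric
    rows that appear in no reaction as substrate) are removed outright.
    """
    import sympy

    S = model.stoichiometric_matrix()
    _, E, _ = model._compiled()
    n = model.n
    # constant species: touched by no reaction at all
    constant = [i for i in range(n) if not S[i].any() and not E[i].any()]
    nullspace = sympy.Matrix(S.T).nullspace()
    if not nullspace and not constant:
        return model

    try:
        M_ref, _ = steady_state_and_jacobian(model)
    except (ArithmeticError, ValueError, RuntimeError):
        M_ref = np.ones(n)

    removed: set[int] = set(constant)
    conservations = list(model.conservations)
    for vec in nullspace:
        w = np.array([float(v) for v in vec], dtype=float)
        candidates = [i for i in np.nonzero(w)[0] if i not in removed]
        if not candidates:
            continue
        dep = max(candidates)
        removed.add(dep)
        coeffs = {model.species[i]: float(w[i]) for i in np.nonzero(w)[0]}
        total = float(w @ M_ref)
        conservations.append((model.species[dep], coeffs, total))

    kept = [s for i, s in enumerate(model.species) if i not in removed]
    reduced = KineticModel(species=kept, reactions=copy.deepcopy(model.reactions),
                           parameters=dict(model.parameters), conservations=conservations)
    return _ReducedKineticModel.promote(reduced, model.species)


class _ReducedKineticModel(KineticModel):
    """KineticModel whose removed species are reconstructed from totals."""

    _full_species: list[str]

    @classmethod
    def promote(cls, model: KineticModel, full_species: list[str]) -> "_ReducedKineticModel":
        obj = cls(species=model.species, reactions=model.reactions,
                  parameters=model.parameters, conservations=model.conservations)
        obj._full_species = list(full_species)
        return obj

    def _full_state(self, M: np.ndarray) -> dict[str, float]:
        state = dict(zip(self.species, np.asarray(M, dtype=float)))
        for removed, coeffs, total in self.conservations:
            if removed not in self._full_species:
                continue
            acc = total
            for sp, c in coeffs.items():
                if sp != removed:
                    acc -= c * state.get(sp, 0.0)
            state[removed] = acc / coeffs[removed]
        return state

    def rates(self, M: np.ndarray) -> np.ndarray:
        state = self._full_state(M)
        v = np.empty(len(self.reactions))
        for r, rx in enumerate(self.reactions):
            rate = self.parameters[rx.rate_param]
            for sp, c in rx.substrates.items():
                rate *= max(state.get(sp, 0.0), 0.0) ** c
            v[r] = rate
        return v

    def f(self, M: np.ndarray) -> np.ndarray:
        v = self.rates(M)
        out = np.zeros(self.n)
        idx = {s: i for i, s in enumerate(self.species)}
        for r, rx in enumerate(self.reactions):
            for sp, c in rx.substrates.items():
                if sp in idx:
                    out[idx[sp]] -= c * v[r]
            for sp, c in rx.products.items():
                if sp in idx:
                    out[idx[sp]] += c * v[r]
        return out

    def analytic_jacobian(self, M: np.ndarray) -> np.ndarray:
        return _finite_difference_jacobian(self, np.asarray(M, dtype=float))


def _finite_difference_jacobian(model: KineticModel, M: np.ndarray) -> np.ndarray:
    n = model.n
    J = np.zeros((n, n))
    for j in range(n):
        h = 1e-6 * max(1.0, abs(M[j]))
        up, dn = M.copy(), M.copy()
        up[j] += h
        dn[j] -= h
        J[:, j] = (model.f(up) - model.f(dn)) / (2 * h)
    return J


def steady_state_and_jacobian(model: KineticModel,
                              M0: np.ndarray | None = None) -> tuple[np.ndarray, Jacobian]:
    """Positive steady state by ODE relaxation plus root polishing.

    The Jacobian is evaluated analytically for plain mass-action models
    and by central finite differences otherwise; convergence requires
    ||F(M*)||_inf <= 1e-10 * max(1, max rate).
    """
    n = model.n
    x0 = np.ones(n) if M0 is None else np.asarray(M0, dtype=float)
    sol = solve_ivp(lambda t, y: model.f(y), (0.0, 200.0), x0, method="LSODA",
                    rtol=1e-9, atol=1e-11)
    if not sol.success:
        raise ArithmeticError(f"relaxation failed: {sol.message}")
    x = np.clip(sol.y[:, -1], 1e-12, None)
    res = root(model.f, x, method="hybr", tol=1e-13)
    if res.success:
        x = res.x
    resid = np.max(np.abs(model.f(x)))
    scale = max(1.0, float(np.max(np.abs(model.rates(np.clip(x, 0, None))))))
    if resid > 1e-10 * scale:
        raise ArithmeticError(f"steady state not converged (residual {resid:g})")
    J = model.analytic_jacobian(x)
    if isinstance(model, _ReducedKineticModel) is False:
        J_fd = _finite_difference_jacobian(model, x)
        denom = max(1.0, np.abs(J).max())
        if np.abs(J - J_fd).max() > 1e-5 * denom:
            raise ArithmeticError("analytic and finite-difference Jacobians disagree")
    return x, Jacobian(values=J)


def covariance_via_lyapunov(J: Jacobian | np.ndarray, eps_d: float,
                            seed: int | None = None,
                            rng: np.random.Generator | None = None,
                            labels: list[str] | None = None,
                            ) -> tuple[CovarianceMatrix, FluctuationMatrix]:
    """Exact covariance from the Lyapunov equation with a randomized D.

    D is diagonal with entries uniform on (1 - eps_d, 1 + eps_d), so
    eps_d = 0 gives the identity fluctuation matrix.
    """
    if not (0 <= eps_d < 1):
        raise ValueError("eps_d must lie in [0, 1)")
    Jv = J.values if isinstance(J, Jacobian) else np.asarray(J, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    d = rng.uniform(1.0 - eps_d, 1.0 + eps_d, size=Jv.shape[0])
    D = FluctuationMatrix(np.diag(d), diagonal_only=True)
    C = solve_forward_lyapunov(Jv, D, labels=labels)
    return C, D


def covariance_via_sde(model: KineticModel, spec: NoiseSpec) -> CovarianceMatrix:
    """Sample covariance from Euler–Maruyama simulation around steady state.

    One long stationary trajectory is integrated from the steady state,
    ``burn_in`` steps are discarded, and ``n_samples`` states are
    recorded every ``thin`` steps.  Concentrations are floored at zero.
    The stationary covariance of this linearized process matches the
    Lyapunov solution with D = (sigma^2 / 2) I.
    """
    M_star, _ = steady_state_and_jacobian(model)
    rng = np.random.default_rng(spec.seed)
    n = model.n
    total = spec.burn_in + spec.n_samples * spec.thin
    sqdt = np.sqrt(spec.dt)
    samples = np.empty((spec.n_samples, n))
    M = M_star.copy()
    kept = 0
    for step in range(total):
        noise = rng.standard_normal(n)
        M = M + model.f(M) * spec.dt + spec.sde_sigma * sqdt * noise
        np.clip(M, 0.0, None, out=M)
        if not np.all(np.isfinite(M)) or np.max(M) > 1e6 * max(1.0, M_star.max()):
            raise ArithmeticError(f"SDE trajectory diverged; reduce dt={spec.dt}")
        if step >= spec.burn_in and (step - spec.burn_in) % spec.thin == spec.thin - 1:
            samples[kept] = M
            kept += 1
    cov = np.cov(samples[:kept], rowvar=False)
    cov = np.atleast_2d(cov)
    return CovarianceMatrix(cov, labels=list(model.species))


def make_condition_pair(model: KineticModel,
                        perturbations: list[tuple[str, float]]) -> ConditionPair:
    """Two-condition pair: reference model vs. parameter-scaled copy."""
    for name, _ in perturbations:
        if name not in model.parameters:
            raise KeyError(f"unknown parameter {name!r}")
    perturbed = copy.deepcopy(model)
    for name, factor in perturbations:
        perturbed.parameters[name] *= factor
    perturbed.invalidate()
    for m, label in ((model, "reference"), (perturbed, "perturbed")):
        _, J = steady_state_and_jacobian(m)
        if not J.is_stable():
            raise ArithmeticError(f"{label} model is not Hurwitz-stable")
    return ConditionPair(model_h=model, model_d=perturbed, perturbed=list(perturbations))


def kinetic_model_to_sbml(model: KineticModel, path) -> None:
    """Serialize a mass-action kinetic model as SBML L3 with kinetic laws."""
    import libsbml

    doc = libsbml.SBMLDocument(3, 2)
    sm = doc.createModel()
    sm.setId("kinetic_model")
    comp = sm.createCompartment()
    comp.setId("c")
    comp.setConstant(True)
    comp.setSize(1.0)
    for sp in model.species:
        s = sm.createSpecies()
        s.setId(sp)
        s.setCompartment("c")
        s.setInitialConcentration(1.0)
        s.setConstant(False)
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
    for pname, val in model.parameters.items():
        p = sm.createParameter()
        p.setId(pname)
        p.setValue(float(val))
        p.setConstant(True)
    for rx in model.reactions:
        r = sm.createReaction()
        r.setId(rx.name)
        r.setReversible(False)
        for sp, c in rx.substrates.items():
            ref = r.createReactant()
            ref.setSpecies(sp)
            ref.setStoichiometry(float(c))
            ref.setConstant(True)
        for sp, c in rx.products.items():
            ref = r.createProduct()
            ref.setSpecies(sp)
            ref.setStoichiometry(float(c))
            ref.setConstant(True)
        terms = [rx.rate_param]
        for sp, c in rx.substrates.items():
            terms.append(sp if c == 1 else f"{sp}^{c:g}")
        kl = r.createKineticLaw()
        kl.setMath(libsbml.parseL3Formula(" * ".join(terms)))
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise OSError(f"could not write SBML to {path}")


def kinetic_model_from_sbml(path) -> KineticModel:
    """Load an SBML model whose kinetic laws are mass-action products.

    Each kinetic law must be a product of one (global or local) rate
    parameter and powers of the reactant species; anything else raises,
    since only mass-action networks admit the analytic Jacobian and
    stability analysis used downstream.
    """
    import libsbml

    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ValueError(f"SBML parse error in {path}")
    sm = doc.getModel()
    species = [s.getId() for s in sm.getListOfSpecies() if not s.getConstant()]
    parameters = {p.getId(): p.getValue() for p in sm.getListOfParameters()}
    reactions: list[KineticReaction] = []
    for rx in sm.getListOfReactions():
        subs = {ref.getSpecies(): ref.getStoichiometry() or 1.0
                for ref in rx.getListOfReactants()}
        prods = {ref.getSpecies(): ref.getStoichiometry() or 1.0
                 for ref in rx.getListOfProducts()}
        kl = rx.getKineticLaw()
        if kl is None:
            raise ValueError(f"reaction {rx.getId()}: no kinetic law")
        for lp in kl.getListOfParameters():
            parameters[f"{rx.getId()}_{lp.getId()}"] = lp.getValue()
        rate_param = _mass_action_rate_param(kl.getMath(), subs, parameters, rx.getId())
        reactions.append(KineticReaction(rx.getId() or f"r{len(reactions)}",
                                         subs, prods, rate_param))
    return KineticModel(species=species, reactions=reactions, parameters=parameters)


def _mass_action_rate_param(ast, substrates, parameters, rxid) -> str:
    """Check that the law is k * prod(substrates^coeff) and return k's name."""
    import libsbml

    factors: list = []

    def collect(node):
        if node.getType() == libsbml.AST_TIMES:
            for i in range(node.getNumChildren()):
                collect(node.getChild(i))
        else:
            factors.append(node)

    collect(ast)
    param = None
    seen: dict[str, float] = {}
    for f in factors:
        t = f.getType()
        if t == libsbml.AST_NAME:
            name = f.getName()
            if name in substrates:
                seen[name] = seen.get(name, 0.0) + 1.0
            elif name in parameters or f"{rxid}_{name}" in parameters:
                if param is not None:
                    raise ValueError(f"reaction {rxid}: not mass action (two parameters)")
                param = name if name in parameters else f"{rxid}_{name}"
            else:
                raise ValueError(f"reaction {rxid}: unknown factor {name!r}")
        elif t == libsbml.AST_POWER or t == libsbml.AST_FUNCTION_POWER:
            base, expo = f.getChild(0), f.getChild(1)
            name = base.getName()
            if base.getType() != libsbml.AST_NAME or name not in substrates:
                raise ValueError(f"reaction {rxid}: non-mass-action power term")
            seen[name] = seen.get(name, 0.0) + expo.getValue()
        elif t in (libsbml.AST_INTEGER, libsbml.AST_REAL):
            continue                         # numeric factor (e.g. compartment size 1)
        else:
            raise ValueError(f"reaction {rxid}: non-mass-action kinetic law")
    if param is None:
        raise ValueError(f"reaction {rxid}: no rate parameter in kinetic law")
    for sp, c in substrates.items():
        if seen.get(sp, 0.0) != c:
            raise ValueError(f"reaction {rxid}: law inconsistent with stoichiometry of {sp}")
    return param


#: fixture sizes matched to the seven evaluation-model sizes (species counts)
FIXTURE_SIZES = (6, 5, 13, 12, 31, 27, 33)

_FIXTURE_SEEDS = {6: 11, 5: 7, 13: 23, 12: 19, 31: 41, 27: 37, 33: 43}


def fixture_model(n_species: int) -> KineticModel:
    """Deterministic packaged fixture model of the given size.

    Fixtures are uni-molecular mass-action networks, so the Jacobian is
    concentration-independent and a rate-constant perturbation changes an
    exactly known set of Jacobian entries — a sharp ground truth for
    recovery benchmarks.
    """
    if n_species not in _FIXTURE_SEEDS:
        raise KeyError(f"no fixture of size {n_species}; available: {sorted(_FIXTURE_SEEDS)}")
    n_reactions = max(n_species - 1, int(round(1.3 * n_species)))
    return generate_mass_action_model(n_species, n_reactions, seed=_FIXTURE_SEEDS[n_species],
                                      bimolecular_fraction=0.0)
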