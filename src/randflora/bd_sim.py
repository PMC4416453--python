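"""Forward birth-death simulation of clades and ultrametric survivor trees.

This is the Monte Carlo counterpart of :mod:`randflora.bd_moments`: an exact,
event-driven (next-event) simulation of a linear birth-death process started
from one founder (stem) or two founders (crown), optionally conditioned on
survival by rejection sampling, with piecewise-constant extinction pulses
emulating episodic aridification waves.

Two backends share the same stochastic model:

* a per-replicate event loop that records the full genealogy, supports
  extinction pulses and emits ultrametric newick trees of the survivors;
* a vectorized constant-rate counts-only loop used for large ensembles where
  only extant clade sizes are needed.

Ages are reported backward from the present (the end of the horizon) in Ma,
matching chronogram conventions: a replicate's stem age is the horizon and
its crown age is the age of the deepest split among surviving lineages.
Everything is driven by an integer-seeded numpy generator; identical seed and
scenario give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import ConditioningError, DomainError, NoSurvivorsError

__all__ = [
    "SimScenario",
    "SimResult",
    "EnsembleSummary",
    "simulate_clade",
    "simulate_ensemble",
    "stem_crown_gap_distribution",
]

Condition = Literal["none", "stem_survival", "crown_survival"]

#: default cap on rejection-sampling attempts when conditioning on survival
REJECTION_CAP = 1_000_000

#: hard cap on concurrently alive lineages (guards runaway supercritical runs)
MAX_LINEAGES = 1_000_000


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one simulation condition.

    ``pulses`` are (older_ma, younger_ma, mu_pulse) intervals measured
    backward from the present; within a pulse the extinction rate is
    ``mu_pulse`` instead of ``mu_background``.  Intervals must lie inside
    [0, horizon] and must not overlap.
    """

    lambda_: float
    mu_background: float
    horizon: float
    pulses: tuple[tuple[float, float, float], ...] = ()
    condition: Condition = "none"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.lambda_ >= 0.0:
            raise DomainError(f"lambda_={self.lambda_!r} must be >= 0")
        if not self.mu_background >= 0.0:
            raise DomainError(f"mu_background={self.mu_background!r} must be >= 0")
        if not self.horizon > 0.0:
            raise DomainError(f"horizon={self.horizon!r} must be > 0")
        if self.condition not in ("none", "stem_survival", "crown_survival"):
            raise DomainError(f"condition={self.condition!r} unknown")
        norm = []
        for pulse in self.pulses:
            if len(pulse) != 3:
                raise DomainError(f"pulse {pulse!r} must be (older, younger, mu)")
            older, younger, mu = (float(x) for x in pulse)
            if older < younger:
                older, younger = younger, older
            if mu < 0.0:
                raise DomainError(f"pulse {pulse!r}: mu must be >= 0")
            if younger < 0.0 or older > self.horizon:
                raise DomainError(
                    f"pulse {pulse!r} outside [0, horizon={self.horizon}]"
                )
            norm.append((older, younger, mu))
        norm.sort(key=lambda p: -p[0])
        for (o1, y1, _), (o2, y2, _) in zip(norm, norm[1:]):
            if o2 > y1:
                raise DomainError("pulses overlap")
        object.__setattr__(self, "pulses", tuple(norm))

    @property
    def n_founders(self) -> int:
        return 2 if self.condition == "crown_survival" else 1

    @classmethod
    def from_config(cls, text: str) -> "SimScenario":
        """Parse a flat ``key = value`` scenario file.

        Recognized keys: lambda, mu, horizon, condition, seed, and repeatable
        ``pulse = older younger mu`` lines.  Blank lines and ``#`` comments
        are ignored.
        """
        kw: dict = {"pulses": []}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise DomainError(f"scenario line {lineno}: expected key = value")
            key, value = (part.strip() for part in line.split("=", 1))
            if key in ("lambda", "lambda_"):
                kw["lambda_"] = float(value)
            elif key in ("mu", "mu_background"):
                kw["mu_background"] = float(value)
            elif key == "horizon":
                kw["horizon"] = float(value)
            elif key == "condition":
                kw["condition"] = value
            elif key == "seed":
                kw["seed"] = int(value)
            elif key == "pulse":
                parts = value.split()
                if len(parts) != 3:
                    raise DomainError(
                        f"scenario line {lineno}: pulse needs 'older younger mu'"
                    )
                kw["pulses"].append(tuple(float(p) for p in parts))
            else:
                raise DomainError(f"scenario line {lineno}: unknown key {key!r}")
        kw["pulses"] = tuple(kw["pulses"])
        missing = {"lambda_", "mu_background", "horizon"} - kw.keys()
        if missing:
            raise DomainError(f"scenario missing keys: {sorted(missing)}")
        return cls(**kw)


@dataclass(frozen=True)
class SimResult:
    """Outcome of one replicate.

    ``crown_age`` is the age (Ma before present) of the deepest split among
    surviving lineages, absent with fewer than two survivors; ``stem_age`` is
    the horizon.  ``tree`` is a newick string of the survivors (branch
    lengths in Myr) when requested.
    """

    extant_count: int
    tree: str | None
    crown_age: float | None
    stem_age: float


@dataclass(frozen=True)
class EnsembleSummary:
    mean: float
    variance: float
    tails: dict[int, float] = field(default_factory=dict)


# ----------------------------------------------------------------------
# genealogy-tracking event loop


class _Genealogy:
    """Flat arrays describing one realized genealogy (forward time)."""

    __slots__ = ("birth_time", "death_time", "births", "alive", "horizon")

    def __init__(self, n_founders: int, horizon: float) -> None:
        self.birth_time = [0.0] * n_founders
        self.death_time: list[float | None] = [None] * n_founders
        self.births: list[list[tuple[float, int]]] = [[] for _ in range(n_founders)]
        self.alive = list(range(n_founders))
        self.horizon = horizon

    @property
    def survivors(self) -> list[int]:
        return list(self.alive)


def _forward_segments(
    scenario: SimScenario,
) -> list[tuple[float, float, float]]:
    """Piecewise-constant extinction rate as (start, end, mu) in forward time."""
    h = scenario.horizon
    edges = {0.0, h}
    for older, younger, _ in scenario.pulses:
        edges.add(h - older)
        edges.add(h - younger)
    cuts = sorted(edges)
    segments = []
    for s0, s1 in zip(cuts, cuts[1:]):
        age_mid = h - 0.5 * (s0 + s1)
        mu = scenario.mu_background
        for older, younger, mu_pulse in scenario.pulses:
            if younger < age_mid <= older:
                mu = mu_pulse
                break
        segments.append((s0, s1, mu))
    return segments


def _run_genealogy(
    scenario: SimScenario, rng: np.random.Generator
) -> _Genealogy:
    lam = scenario.lambda_
    segments = _forward_segments(scenario)
    gen = _Genealogy(scenario.n_founders, scenario.horizon)
    alive = gen.alive
    s = 0.0
    for seg_start, seg_end, mu in segments:
        total_per_lineage = lam + mu
        if s < seg_start:
            s = seg_start
        while alive:
            if total_per_lineage <= 0.0:
                s = seg_end
                break
            dt = rng.exponential() / (len(alive) * total_per_lineage)
            if s + dt >= seg_end:
                s = seg_end
                break
            s += dt
            pos = int(rng.integers(len(alive)))
            lineage = alive[pos]
            if rng.random() < lam / total_per_lineage:
                child = len(gen.birth_time)
                if child >= MAX_LINEAGES:
                    raise DomainError(
                        f"lineage count exceeded MAX_LINEAGES={MAX_LINEAGES}"
                    )
                gen.birth_time.append(s)
                gen.death_time.append(None)
                gen.births.append([])
                gen.births[lineage].append((s, child))
                alive.append(child)
            else:
                gen.death_time[lineage] = s
                alive[pos] = alive[-1]
                alive.pop()
        if not alive:
            break
    return gen


def _founder_survives(gen: _Genealogy, founder: int) -> bool:
    """Depth-first check that `founder` has at least one surviving descendant."""
    stack = [founder]
    alive = set(gen.alive)
    while stack:
        lid = stack.pop()
        if lid in alive:
            return True
        stack.extend(child for _, child in gen.births[lid])
    return False


def _condition_met(gen: _Genealogy, condition: Condition) -> bool:
    if condition == "none":
        return True
    if condition == "stem_survival":
        return len(gen.alive) >= 1
    return _founder_survives(gen, 0) and _founder_survives(gen, 1)


def _survivor_forest(gen: _Genealogy) -> list[object]:
    """Pruned survivor subtree per founder.

    Nodes are ``("leaf", lineage_id)`` or ``(split_time, left, right)``;
    founders without surviving descendants yield ``None``.  Children have
    larger ids than parents, so a reverse-id sweep needs no recursion.
    """
    n = len(gen.birth_time)
    alive = set(gen.alive)
    sub: list[object] = [None] * n
    for lid in range(n - 1, -1, -1):
        node: object = ("leaf", lid) if lid in alive else None
        for t, child in reversed(gen.births[lid]):
            s = sub[child]
            if s is None:
                continue
            node = (t, node, s) if node is not None else s
        sub[lid] = node
    # founders are exactly the lineages with birth_time == 0
    founders = sum(1 for bt in gen.birth_time[:2] if bt == 0.0)
    return [sub[i] for i in range(founders)]


def _join_forest(forest: list[object]) -> object:
    present = [node for node in forest if node is not None]
    if not present:
        return None
    if len(present) == 1:
        return present[0]
    return (0.0, present[0], present[1])


def _crown_split_time(root: object) -> float | None:
    if root is None or root[0] == "leaf":
        return None
    return float(root[0])


def _newick(node: object, parent_time: float, horizon: float) -> str:
    if node[0] == "leaf":
        return f"t{node[1]}:{horizon - parent_time!r}"
    t, left, right = node
    inner = (
        f"({_newick(left, t, horizon)},{_newick(right, t, horizon)})"
    )
    return f"{inner}:{t - parent_time!r}"


def _tree_string(root: object, horizon: float) -> str | None:
    if root is None:
        return None
    if root[0] == "leaf":
        return f"t{root[1]}:{horizon!r};"
    t, left, right = root
    return (
        f"({_newick(left, t, horizon)},{_newick(right, t, horizon)})"
        f":{t!r};"
    )


def _result_from_genealogy(
    gen: _Genealogy, keep_tree: bool
) -> SimResult:
    forest = _survivor_forest(gen)
    root = _join_forest(forest)
    split = _crown_split_time(root)
    crown_age = gen.horizon - split if split is not None else None
    tree = _tree_string(root, gen.horizon) if keep_tree else None
    return SimResult(
        extant_count=len(gen.alive),
        tree=tree,
        crown_age=crown_age,
        stem_age=gen.horizon,
    )


# ----------------------------------------------------------------------
# vectorized constant-rate counts


def _counts_constant(
    rng: np.random.Generator,
    lam: float,
    mu: float,
    horizon: float,
    reps: int,
) -> np.ndarray:
    """Extant counts of `reps` independent single-founder replicates."""
    total = lam + mu
    if total <= 0.0:
        return np.ones(reps, dtype=np.int64)
    k = np.ones(reps, dtype=np.int64)
    t = np.zeros(reps)
    out = np.ones(reps, dtype=np.int64)
    idx = np.arange(reps)
    p_birth = lam / total
    while idx.size:
        t[idx] += rng.exponential(size=idx.size) / (k[idx] * total)
        crossed = t[idx] >= horizon
        if crossed.any():
            done = idx[crossed]
            out[done] = k[done]
            idx = idx[~crossed]
            if idx.size == 0:
                break
        births = rng.random(idx.size) < p_birth
        k[idx] += np.where(births, 1, -1)
        if k[idx].max(initial=0) > MAX_LINEAGES:
            raise DomainError(
                f"lineage count exceeded MAX_LINEAGES={MAX_LINEAGES}"
            )
        extinct = k[idx] == 0
        if extinct.any():
            out[idx[extinct]] = 0
            idx = idx[~extinct]
    return out


def _surviving_counts_constant(
    rng: np.random.Generator,
    lam: float,
    mu: float,
    horizon: float,
    need: int,
    cap: int,
) -> np.ndarray:
    """Counts of single founders conditioned on >= 1 survivor (rejection)."""
    got: list[np.ndarray] = []
    have = 0
    attempts = 0
    frac = 0.5  # running survival-fraction estimate, refined per batch
    while have < need:
        batch = min(
            max(1024, int((need - have) / max(frac, 1e-3) * 1.2)),
            max(cap - attempts, 0),
        )
        if batch == 0:
            raise ConditioningError(
                f"survival condition not met within rejection cap {cap}"
            )
        counts = _counts_constant(rng, lam, mu, horizon, batch)
        attempts += batch
        kept = counts[counts > 0]
        got.append(kept)
        have += kept.size
        frac = max(have / attempts, 1e-6)
    return np.concatenate(got)[:need]


# ----------------------------------------------------------------------
# public API


def _rng_for(scenario: SimScenario, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(scenario.seed)


def simulate_clade(
    scenario: SimScenario,
    *,
    rng: np.random.Generator | None = None,
    keep_tree: bool = False,
    rejection_cap: int = REJECTION_CAP,
) -> SimResult:
    """Simulate one clade under ``scenario``.

    Conditioning (stem or crown survival) is implemented by rejection: the
    replicate is re-drawn until the condition holds, up to ``rejection_cap``
    attempts.
    """
    rng = _rng_for(scenario, rng)
    for _ in range(rejection_cap):
        gen = _run_genealogy(scenario, rng)
        if _condition_met(gen, scenario.condition):
            return _result_from_genealogy(gen, keep_tree)
    raise ConditioningError(
        f"condition {scenario.condition!r} not met in {rejection_cap} rejections"
    )


def _fast_path_ok(scenario: SimScenario, keep_trees: bool) -> bool:
    return not keep_trees and not scenario.pulses


def simulate_ensemble(
    scenario: SimScenario,
    reps: int,
    *,
    tail_at: Iterable[int] = (),
    keep_trees: bool = False,
    rejection_cap: int = REJECTION_CAP,
) -> tuple[list[SimResult], EnsembleSummary]:
    """Draw ``reps`` independent replicates and summarize extant counts.

    For constant-rate scenarios without tree output a vectorized counts-only
    backend is used (same stochastic model, same per-seed determinism).  The
    summary reports the sample mean and (population) variance of extant
    counts and the empirical tail frequency P(N >= n) at each requested n.
    """
    if reps < 1:
        raise DomainError(f"reps={reps!r} must be >= 1")
    rng = _rng_for(scenario, rng=None)

    if _fast_path_ok(scenario, keep_trees):
        lam, mu, h = scenario.lambda_, scenario.mu_background, scenario.horizon
        if scenario.condition == "none":
            counts = _counts_constant(rng, lam, mu, h, reps)
            results = [SimResult(int(c), None, None, h) for c in counts]
        elif scenario.condition == "stem_survival":
            counts = _surviving_counts_constant(rng, lam, mu, h, reps, rejection_cap)
            results = [SimResult(int(c), None, None, h) for c in counts]
        else:  # crown_survival: two independent conditioned founders
            halves = _surviving_counts_constant(
                rng, lam, mu, h, 2 * reps, rejection_cap
            )
            counts = halves[:reps] + halves[reps:]
            # both founders survive, so the deepest surviving split is the origin
            results = [SimResult(int(c), None, h, h) for c in counts]
    else:
        results = [
            simulate_clade(
                scenario, rng=rng, keep_tree=keep_trees, rejection_cap=rejection_cap
            )
            for _ in range(reps)
        ]
        counts = np.array([res.extant_count for res in results], dtype=np.int64)

    tails = {
        int(n): float(np.mean(counts >= int(n))) for n in tail_at
    }
    summary = EnsembleSummary(
        mean=float(np.mean(counts)),
        variance=float(np.var(counts)),
        tails=tails,
    )
    return results, summary


def stem_crown_gap_distribution(
    scenario: SimScenario,
    reps: int,
    *,
    rejection_cap: int = REJECTION_CAP,
) -> np.ndarray:
    """Stem-age minus crown-age gaps across surviving replicates.

    Each replicate with at least two survivors contributes
    ``horizon - crown_age``; replicates with fewer survivors are skipped.
    Raises :class:`NoSurvivorsError` when no replicate qualifies.
    """
    if reps < 1:
        raise DomainError(f"reps={reps!r} must be >= 1")
    rng = _rng_for(scenario, rng=None)
    gaps = []
    for _ in range(reps):
        res = simulate_clade(scenario, rng=rng, rejection_cap=rejection_cap)
        if res.crown_age is not None:
            gaps.append(res.stem_age - res.crown_age)
    if not gaps:
        raise NoSurvivorsError(
            "no replicate produced >= 2 survivors; gap distribution empty"
        )
    return np.asarray(gaps)


def with_seed(scenario: SimScenario, seed: int) -> SimScenario:
    """Return a copy of ``scenario`` with a different seed."""
    return replace(scenario, seed=seed)
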