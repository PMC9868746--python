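"""Scenario fixtures and synthetic parameter sampling.

Three printed parameter sets drive the headline simulations; each
stabilises a different corner of the game:

* Scenario A (bribe K=30 below the agency's concealment cost Vt=40):
  E1=(0,0,0) — high quality, honest agencies, lax supervision.
* Scenario B (A with K raised to 100): E5=(1,1,0) — low quality, bribed
  agencies, still-lax supervision (credibility loss Pg=20 too small to
  justify the regulation cost Cr=120).
* Scenario C (B with Pg raised to 100): E8=(1,1,1) — misconduct persists
  but the regulator is forced into strict supervision.

Random valid parameter sets, optionally targeted at the stability regime
of E1, E5 or E8, support property testing and the feasibility cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import PARAM_KEYS, ParameterSet, validate_parameters

#: Upper bound of the per-parameter uniform proposal; brackets every
#: printed value.
SAMPLING_HIGH: float = 500.0

#: Parameters entering the standing inequality constraints.
_CONSTRAINED = ("Ee", "Ch", "Cl", "K", "Ve", "Pe", "Se")
#: Parameters unconstrained by the standing inequalities.
_FREE = tuple(k for k in PARAM_KEYS if k not in _CONSTRAINED)

_PRINTED_A = dict(
    Ee=500.0, Ch=180.0, Cl=30.0, Ve=20.0, K=30.0, Pe=10.0, Se=15.0,
    Vt=40.0, Pt=30.0, St=20.0, Cr=120.0, Pg=20.0,
    Et=0.0, Eg=0.0, Gg=0.0,
)


@dataclass(frozen=True)
class Scenario:
    name: str
    params: ParameterSet
    provenance: str  # "printed" | "sampled"
    seed: int | None = None


def printed_sets() -> dict[str, Scenario]:
    """The three printed simulation parameter sets, keyed 'A', 'B', 'C'."""
    a = ParameterSet(**_PRINTED_A)
    b = a.replace(K=100.0)
    c = b.replace(Pg=100.0)
    return {
        "A": Scenario("A", a, "printed"),
        "B": Scenario("B", b, "printed"),
        "C": Scenario("C", c, "printed"),
    }


def scenario(name: str) -> Scenario:
    """Printed scenario by name ('A', 'B' or 'C')."""
    sets = printed_sets()
    if name not in sets:
        raise KeyError(f"unknown scenario {name!r}; printed scenarios are A, B, C")
    return sets[name]


def _standing_mask(block: np.ndarray) -> np.ndarray:
    """Vectorised standing-constraint check on a (n, 7) constrained block."""
    Ee, Ch, Cl, K, Ve, Pe, Se = block.T
    return (Ee > Ch) & (Ch > Cl) & (Ch > Cl + K + Ve + Pe + Se)


def _regime_mask(regime: str, p: dict[str, np.ndarray]) -> np.ndarray:
    if regime == "E1":
        return p["K"] - p["Vt"] < 0
    if regime == "E5":
        return (p["Vt"] - p["K"] < 0) & (
            p["Pe"] - p["Cr"] + p["Pg"] + p["Pt"] + p["Se"] + p["St"] < 0
        )
    if regime == "E8":
        return (p["Vt"] - p["K"] + p["St"] + p["Pt"] < 0) & (
            p["Cr"] - p["Pe"] - p["Pg"] - p["Pt"] - p["Se"] - p["St"] < 0
        )
    raise ValueError(f"unknown regime {regime!r}")


class SamplingBudgetExceeded(RuntimeError):
    """Raised when rejection sampling exhausts its draw budget."""


def sample_parameters(
    regime: str = "any",
    seed: int = 0,
    n: int = 1,
    max_draws: int = 1_000_000,
    high: float = SAMPLING_HIGH,
) -> list[Scenario]:
    """Sample ``n`` valid parameter sets, optionally targeting a regime.

    Every parameter is proposed uniformly on ``[0, high]``. For
    ``regime="any"`` and ``"E1"``, full sets are rejection-sampled until
    the standing constraints (and the E1 predicate) hold; because the
    constraints involve only the manufacturer-side block, that block is
    resampled separately, which keeps the accepted draws exactly uniform
    on the constrained region. For the rare regimes ``"E5"`` and ``"E8"``
    the free block (Vt, Pt, St, Cr, Pg, ...) is resampled conditionally on
    each accepted constrained block until the corner's stability predicate
    holds, redrawing the constrained block if the predicate resists; the
    result is uniform per parameter but only approximately uniform on the
    joint regime region (plain joint rejection there accepts ~5e-7 of
    draws and is impractical).

    Raises ``SamplingBudgetExceeded`` after ``max_draws`` proposals.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if regime not in ("any", "E1", "E5", "E8"):
        raise ValueError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(seed)
    out: list[Scenario] = []
    draws = 0
    batch = 50_000

    def make(block_c: np.ndarray, block_f: np.ndarray, idx: int) -> Scenario:
        d = dict(zip(_CONSTRAINED, (float(v) for v in block_c)))
        d.update(zip(_FREE, (float(v) for v in block_f)))
        ps = ParameterSet(**d)
        assert not validate_parameters(ps)
        return Scenario(f"{regime}-{seed}-{idx}", ps, "sampled", seed)

    if regime in ("any", "E1"):
        while len(out) < n:
            if draws >= max_draws:
                raise SamplingBudgetExceeded(
                    f"no {n} '{regime}' sets within {max_draws} draws"
                )
            bc = rng.uniform(0, high, size=(batch, len(_CONSTRAINED)))
            bf = rng.uniform(0, high, size=(batch, len(_FREE)))
            draws += batch
            ok = _standing_mask(bc)
            if regime == "E1":
                cols = {k: bc[:, _CONSTRAINED.index(k)] for k in ("K",)}
                cols["Vt"] = bf[:, _FREE.index("Vt")]
                ok &= _regime_mask("E1", cols)
            for i in np.flatnonzero(ok):
                if len(out) >= n:
                    break
                out.append(make(bc[i], bf[i], len(out)))
        return out

    # Rare regimes: conditional resampling of the free block. Valid
    # constrained blocks are queued so a batch is not wasted on one block.
    free_batch = 20_000
    block_queue: list[np.ndarray] = []
    while len(out) < n:
        while not block_queue:
            if draws >= max_draws:
                raise SamplingBudgetExceeded(
                    f"no {n} '{regime}' sets within {max_draws} draws"
                )
            bc = rng.uniform(0, high, size=(batch, len(_CONSTRAINED)))
            draws += batch
            block_queue.extend(bc[_standing_mask(bc)])
        bc_row = block_queue.pop(0)
        if draws >= max_draws:
            raise SamplingBudgetExceeded(
                f"no {n} '{regime}' sets within {max_draws} draws"
            )
        bf = rng.uniform(0, high, size=(free_batch, len(_FREE)))
        draws += free_batch
        cols = {k: np.full(free_batch, bc_row[_CONSTRAINED.index(k)])
                for k in _CONSTRAINED}
        cols.update({k: bf[:, _FREE.index(k)] for k in _FREE})
        hit = np.flatnonzero(_regime_mask(regime, cols))
        if hit.size:
            out.append(make(bc_row, bf[hit[0]], len(out)))
        # else: predicate resisted for this block; move to the next block
    return out
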