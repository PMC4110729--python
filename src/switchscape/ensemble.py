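"""Monte-Carlo protocol over critical RBN ensembles with embedded switches.

The experiment loop, per network type (no motif, or one/two copies of one
of the four switches):

1. draw a critical RBN;
2. embed 0/1/2 identical motif copies;
3. enumerate attractors; reject the network if it has fewer than
   ``min_attractors`` (default 5 — enough distinct "cell types" to carry a
   lineage-tree structure);
4. build the noisy transition matrix and the all-pairs attractor MFPT
   matrix;
5. orient and classify every attractor pair (directional / separate /
   neither).

Every attempt draws its RNG from a :class:`numpy.random.SeedSequence`
keyed by ``(master_seed, type_index, attempt_index)``, so each type is
independently reproducible and the rejection decisions cannot bias the
accepted networks' streams.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .boolean_core import find_attractors
from .errors import ConfigurationError, EnsembleBudgetError, SwitchscapeError
from .landscape import (
    DEFAULT_DIR_RATIO_THRESHOLD,
    DEFAULT_SEP_THRESHOLD,
    PairRecord,
    density_grid,
    pair_records,
)
from .markov import attractor_mfpt_matrix
from .motifs import MotifKind, embed_motifs
from .barriers import attractor_hamming, transitory_flip_matrix
from .rbn import RbnConfig, generate_critical_rbn

__all__ = [
    "NETWORK_TYPES",
    "parse_network_type",
    "EnsembleConfig",
    "NetworkResult",
    "TypeResult",
    "EnsembleResult",
    "run_type",
    "run_ensemble",
    "pairs_frame",
    "summary_frame",
    "bootstrap_fraction_ci",
    "bootstrap_contrast_ci",
    "villani_mfpt_scatter",
    "hamming_mfpt_scatter",
    "write_outputs",
]

#: The nine network types studied: a bare critical RBN plus one or two
#: identical copies of each switch.
NETWORK_TYPES: tuple[str, ...] = (
    "none",
    "BSx1",
    "BSx2",
    "MI00x1",
    "MI00x2",
    "MI0+x1",
    "MI0+x2",
    "MI++x1",
    "MI++x2",
)


def parse_network_type(name: str) -> tuple[Optional[MotifKind], int]:
    """``"MI0+x2"`` -> ``(MotifKind.MI0P, 2)``; ``"none"`` -> ``(None, 0)``."""
    key = str(name).strip()
    if key.lower() == "none":
        return None, 0
    if "x" not in key:
        raise ConfigurationError(f"unknown network type {name!r}")
    kind_s, _, copies_s = key.rpartition("x")
    try:
        kind = MotifKind.parse(kind_s)
    except SwitchscapeError as e:
        raise ConfigurationError(f"unknown network type {name!r}") from e
    copies = int(copies_s)
    if copies not in (1, 2):
        raise ConfigurationError(f"copies must be 1 or 2 in type {name!r}")
    return kind, copies


@dataclass(frozen=True)
class EnsembleConfig:
    """Full parameterisation of one ensemble run (all of it lands in the
    provenance block of the output)."""

    networks_per_type: int = 200
    network_types: tuple[str, ...] = NETWORK_TYPES
    min_attractors: int = 5
    n_values: tuple[int, ...] = (8, 9, 10)
    q: int = 2
    p_N: Optional[float] = None
    allow_self_input: bool = True
    p_e: float = 0.01
    dir_ratio_threshold: float = DEFAULT_DIR_RATIO_THRESHOLD
    sep_threshold: float = DEFAULT_SEP_THRESHOLD
    master_seed: int = 0
    max_attempts_per_network: int = 500

    def __post_init__(self):
        if self.networks_per_type < 1:
            raise ConfigurationError("networks_per_type must be >= 1")
        if self.min_attractors < 2:
            raise ConfigurationError("min_attractors must be >= 2")
        bad = [t for t in self.network_types if t not in NETWORK_TYPES]
        if bad:
            raise ConfigurationError(f"unknown network types {bad}")


@dataclass(frozen=True)
class NetworkResult:
    """One accepted network's contribution to an ensemble."""

    type_name: str
    network_index: int
    attempt_index: int
    n: int
    num_attractors: int
    pairs: tuple[PairRecord, ...]

    def fraction(self, label: str) -> float:
        if not self.pairs:
            return 0.0
        return sum(p.label == label for p in self.pairs) / len(self.pairs)


@dataclass(frozen=True)
class TypeResult:
    type_name: str
    networks: tuple[NetworkResult, ...]
    attempts: int

    @property
    def all_pairs(self) -> list[PairRecord]:
        return [p for nw in self.networks for p in nw.pairs]

    def fraction(self, label: str) -> float:
        pairs = self.all_pairs
        if not pairs:
            return float("nan")
        return sum(p.label == label for p in pairs) / len(pairs)


@dataclass(frozen=True)
class EnsembleResult:
    config: EnsembleConfig
    types: dict[str, TypeResult]
    errors: dict[str, str]

    @property
    def summary(self) -> pd.DataFrame:
        return summary_frame(self.types)

    @property
    def provenance(self) -> dict:
        d = dataclasses.asdict(self.config)
        d["network_types"] = list(d["network_types"])
        d["n_values"] = list(d["n_values"])
        return {
            "software": "switchscape",
            "version": __version__,
            "config": d,
            "attempts": {t: r.attempts for t, r in self.types.items()},
            "accepted": {t: len(r.networks) for t, r in self.types.items()},
            "errors": self.errors,
        }


def _attempt_rng(master_seed: int, type_index: int, attempt: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(type_index, attempt))
    return np.random.default_rng(ss)


def run_type(type_name: str, config: EnsembleConfig) -> TypeResult:
    """Run the accept/reject loop for one network type.

    Raises :class:`EnsembleBudgetError` (carrying the partial result) when
    ``max_attempts_per_network * networks_per_type`` attempts are used up
    before enough networks are accepted.
    """
    kind, copies = parse_network_type(type_name)
    type_index = NETWORK_TYPES.index(type_name)
    budget = config.max_attempts_per_network * config.networks_per_type
    accepted: list[NetworkResult] = []
    attempt = 0
    while len(accepted) < config.networks_per_type:
        if attempt >= budget:
            partial = TypeResult(
                type_name=type_name, networks=tuple(accepted), attempts=attempt
            )
            raise EnsembleBudgetError(
                f"type {type_name}: only {len(accepted)} of "
                f"{config.networks_per_type} networks accepted in {attempt} attempts",
                partial=partial,
            )
        rng = _attempt_rng(config.master_seed, type_index, attempt)
        attempt += 1
        n = int(rng.choice(config.n_values))
        net = generate_critical_rbn(
            RbnConfig(
                n=n,
                q=config.q,
                p_N=config.p_N,
                allow_self_input=config.allow_self_input,
            ),
            rng=rng,
        )
        if copies:
            net, _ = embed_motifs(net, kind, copies, rng=rng)
        atts = find_attractors(net)
        if len(atts) < config.min_attractors:
            continue
        mfpt = attractor_mfpt_matrix(net, config.p_e, atts)
        pairs = pair_records(
            mfpt, config.dir_ratio_threshold, config.sep_threshold
        )
        accepted.append(
            NetworkResult(
                type_name=type_name,
                network_index=len(accepted),
                attempt_index=attempt - 1,
                n=n,
                num_attractors=len(atts),
                pairs=tuple(pairs),
            )
        )
    return TypeResult(type_name=type_name, networks=tuple(accepted), attempts=attempt)


def run_ensemble(config: EnsembleConfig) -> EnsembleResult:
    """Run all configured types; one failing type does not abort the rest."""
    types: dict[str, TypeResult] = {}
    errors: dict[str, str] = {}
    for type_name in config.network_types:
        try:
            types[type_name] = run_type(type_name, config)
        except EnsembleBudgetError as e:
            types[type_name] = e.partial
            errors[type_name] = str(e)
        except SwitchscapeError as e:  # pragma: no cover - defensive isolation
            errors[type_name] = str(e)
    return EnsembleResult(config=config, types=types, errors=errors)


# ---------------------------------------------------------------------------
# Tabular views and resampling
# ---------------------------------------------------------------------------

def pairs_frame(result: EnsembleResult | TypeResult) -> pd.DataFrame:
    """All pair records as one tidy table."""
    types = result.types.values() if isinstance(result, EnsembleResult) else [result]
    rows = []
    for tr in types:
        for nw in tr.networks:
            for p in nw.pairs:
                rows.append(
                    {
                        "type": tr.type_name,
                        "network_index": nw.network_index,
                        "attempt_index": nw.attempt_index,
                        "n": nw.n,
                        "num_attractors": nw.num_attractors,
                        "attractor_i": p.attractor_i,
                        "attractor_j": p.attractor_j,
                        "forward_mfpt": p.forward_mfpt,
                        "reverse_mfpt": p.reverse_mfpt,
                        "label": p.label,
                        "tie": p.tie,
                    }
                )
    return pd.DataFrame(rows)


def summary_frame(types: dict[str, TypeResult]) -> pd.DataFrame:
    rows = []
    for name, tr in types.items():
        pairs = tr.all_pairs
        rows.append(
            {
                "type": name,
                "networks": len(tr.networks),
                "attempts": tr.attempts,
                "pairs": len(pairs),
                "fraction_separate": tr.fraction("separate"),
                "fraction_directional": tr.fraction("directional"),
                "fraction_neither": tr.fraction("neither"),
            }
        )
    return pd.DataFrame(rows).set_index("type")


def _pooled_fraction(networks: Sequence[NetworkResult], label: str) -> float:
    total = sum(len(nw.pairs) for nw in networks)
    if total == 0:
        return float("nan")
    return sum(sum(p.label == label for p in nw.pairs) for nw in networks) / total


def bootstrap_fraction_ci(
    tr: TypeResult,
    label: str,
    n_boot: int = 1000,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI (resampling networks) of a pooled label fraction."""
    if rng is None:
        rng = np.random.default_rng(0)
    nets = tr.networks
    stats = np.empty(n_boot)
    for b in range(n_boot):
        sample = [nets[i] for i in rng.integers(0, len(nets), size=len(nets))]
        stats[b] = _pooled_fraction(sample, label)
    return tuple(np.nanquantile(stats, [alpha / 2, 1 - alpha / 2]))


def bootstrap_contrast_ci(
    tr_a: TypeResult,
    tr_b: TypeResult,
    label: str,
    n_boot: int = 1000,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Bootstrap CI of ``fraction(a) - fraction(b)`` (independent resampling)."""
    if rng is None:
        rng = np.random.default_rng(0)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        sa = [tr_a.networks[i] for i in rng.integers(0, len(tr_a.networks), len(tr_a.networks))]
        sb = [tr_b.networks[i] for i in rng.integers(0, len(tr_b.networks), len(tr_b.networks))]
        stats[b] = _pooled_fraction(sa, label) - _pooled_fraction(sb, label)
    return tuple(np.nanquantile(stats, [alpha / 2, 1 - alpha / 2]))


# ---------------------------------------------------------------------------
# Barrier-measure comparison experiments
# ---------------------------------------------------------------------------

def villani_mfpt_scatter(
    num_networks: int = 100,
    n: int = 8,
    q: int = 2,
    p_e: float = 0.01,
    seed: int = 0,
    min_attractors: int = 5,
    max_attempts: int = 100_000,
) -> pd.DataFrame:
    """Per ordered attractor pair: MFPT(i, j) versus the transitory
    bit-flip probability P(i, j), over critical RBNs with at least
    ``min_attractors`` attractors."""
    rows = []
    accepted = 0
    attempt = 0
    while accepted < num_networks:
        if attempt >= max_attempts:
            raise EnsembleBudgetError(
                f"only {accepted}/{num_networks} networks found in {attempt} attempts"
            )
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(101, attempt))
        )
        attempt += 1
        net = generate_critical_rbn(RbnConfig(n=n, q=q), rng=rng)
        atts = find_attractors(net)
        if len(atts) < min_attractors:
            continue
        mfpt = attractor_mfpt_matrix(net, p_e, atts)
        flips = transitory_flip_matrix(net, atts)
        k = len(atts)
        for i in range(k):
            for j in range(k):
                if i != j:
                    rows.append(
                        {
                            "network": accepted,
                            "attractor_i": mfpt.attractor_ids[i],
                            "attractor_j": mfpt.attractor_ids[j],
                            "mfpt": float(mfpt.values[i, j]),
                            "flip_probability": float(flips.P[i, j]),
                        }
                    )
        accepted += 1
    return pd.DataFrame(rows)


def hamming_mfpt_scatter(
    num_networks: int = 100,
    n: int = 8,
    q: int = 2,
    p_e: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Per unordered attractor pair: mean attractor Hamming distance versus
    the average of forward and reverse MFPT, over ``num_networks`` critical
    RBNs (networks with fewer than two attractors contribute no pairs)."""
    rows = []
    for draw in range(num_networks):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(202, draw))
        )
        net = generate_critical_rbn(RbnConfig(n=n, q=q), rng=rng)
        atts = find_attractors(net)
        if len(atts) < 2:
            continue
        mfpt = attractor_mfpt_matrix(net, p_e, atts)
        k = len(atts)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    {
                        "network": draw,
                        "attractor_i": mfpt.attractor_ids[i],
                        "attractor_j": mfpt.attractor_ids[j],
                        "hamming": attractor_hamming(
                            atts.attractors[i], atts.attractors[j]
                        ),
                        "mean_mfpt": float(
                            (mfpt.values[i, j] + mfpt.values[j, i]) / 2.0
                        ),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Output writing
# ---------------------------------------------------------------------------

def write_outputs(result: EnsembleResult, outdir) -> None:
    """Write pairs.csv, summary.csv, per-type density grids and provenance.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pairs_frame(result).to_csv(outdir / "pairs.csv", index=False)
    result.summary.to_csv(outdir / "summary.csv")
    for name, tr in result.types.items():
        pairs = tr.all_pairs
        if not pairs:
            continue
        grid = density_grid(pairs, normalized=True)
        safe = name.replace("+", "p")
        pd.DataFrame(grid.hist).to_csv(
            outdir / f"density_{safe}.csv", index=False, header=False
        )
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=1)
        fh.write("\n")
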