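"""Synthetic expression studies with planted cross-shaped triplets.

The generator builds a genes x samples matrix of i.i.d. standard-normal
background noise and plants two kinds of structure on top of it:

* **switch triplets** — a modulator gene X3 and a pair (X1, X2) whose
  correlation differs between the samples where X3 is high and where it is
  low (the "cross-shaped" co-expression pattern). Strata are defined on the
  ranks of the X3 row, so planting commutes with any monotone transform of
  the data — in particular with the rank-based normal quantile transform the
  screening stage applies.
* **differentially expressed genes** — a mean shift (in SD units) added to
  the case samples of selected genes.

Every planted feature is recorded in a :class:`PlantedTruth` object so that
downstream stages can be benchmarked against a known ground truth.

The generative model behind the cross shape is a conditional bivariate
normal: within the upper X3 stratum the pair is drawn with correlation
``rho_high``, within the lower stratum with ``rho_low``, and the middle
samples are left uncorrelated. An optional ``driver_strength`` adds a linear
X3 component to both pair genes, making X3 a marginal (mutual-information
visible) driver of its pair in addition to a correlation switch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "TripletSpec",
    "StudySpec",
    "PlantedTruth",
    "generate_null_matrix",
    "plant_switch_triplet",
    "generate_study",
    "write_truth",
    "read_truth",
]


@dataclass(frozen=True)
class TripletSpec:
    """Specification of one planted switch triplet.

    ``rho_high`` / ``rho_low`` are the pair correlations inside the upper and
    lower X3 strata; ``stratum_fraction`` is the fraction of samples per
    stratum (1/3 reproduces the tertile geometry the screen uses).
    ``driver_strength`` (default 0: pure cross shape) adds
    ``driver_strength * X3`` to both pair genes so the modulator is also a
    marginal driver, e.g. for network-inference benchmarks.
    """

    x3_id: str
    pair_ids: tuple[str, str]
    rho_high: float
    rho_low: float
    stratum_fraction: float = 1.0 / 3.0
    driver_strength: float = 0.0

    def __post_init__(self) -> None:
        ids = {self.x3_id, *self.pair_ids}
        if len(ids) != 3:
            raise ValueError("x3_id and pair_ids must be three distinct genes")
        for rho in (self.rho_high, self.rho_low):
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"correlation {rho} outside [-1, 1]")
        if not 0.0 < self.stratum_fraction <= 0.5:
            raise ValueError("stratum_fraction must be in (0, 0.5]")


@dataclass(frozen=True)
class StudySpec:
    """Full description of a synthetic case/control study.

    ``groups`` maps each sample id to a ``(disease, status)`` pair with
    status ``"case"`` or ``"control"``; :func:`balanced_groups` builds the
    common balanced layout. ``deg_effect`` is the case-group mean shift in SD
    units applied to the first ``n_deg`` genes not consumed by a triplet
    (or to ``deg_ids`` when given explicitly).
    """

    n_genes: int
    n_samples: int
    groups: dict[str, tuple[str, str]] | None = None
    n_deg: int = 0
    deg_effect: float = 0.0
    triplets: tuple[TripletSpec, ...] = ()
    noise_sd: float = 1.0
    seed: int = 0
    deg_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("n_genes and n_samples must be positive")
        if self.n_deg < 0 or self.noise_sd <= 0:
            raise ValueError("n_deg must be >= 0 and noise_sd > 0")
        used = 3 * len(self.triplets)
        if self.n_deg + used > self.n_genes:
            raise ValueError("n_deg plus genes consumed by triplets exceeds n_genes")


@dataclass
class PlantedTruth:
    """Ground-truth record for a generated study."""

    planted_triplets: list[TripletSpec]
    planted_degs: list[tuple[str, float]]
    seed: int
    collisions: list[str] = field(default_factory=list)


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n)]


def _sample_ids(n: int) -> list[str]:
    return [f"s{i:03d}" for i in range(n)]


def balanced_groups(n_samples: int, diseases: tuple[str, ...] = ("D1",)) -> dict[str, tuple[str, str]]:
    """Assign samples to diseases in contiguous blocks, half case half control."""
    ids = _sample_ids(n_samples)
    per = n_samples // len(diseases)
    groups = {}
    for i, sid in enumerate(ids):
        d = diseases[min(i // per, len(diseases) - 1)]
        within = i - min(i // per, len(diseases) - 1) * per
        status = "case" if within < per // 2 else "control"
        groups[sid] = (d, status)
    return groups


def _row_rng(seed: int, stream: tuple[int, ...]) -> np.random.Generator:
    """Substream generator: one global seed, fixed per-operation spawn keys."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=stream))


def generate_null_matrix(n_genes: int, n_samples: int, seed: int) -> ExpressionMatrix:
    """I.i.d. standard-normal background matrix.

    Rows are drawn from independent substreams keyed by row index, so
    enlarging ``n_genes`` leaves existing rows bit-identical.
    """
    if n_genes < 1 or n_samples < 1:
        raise ValueError("matrix dimensions must be positive")
    rows = np.empty((n_genes, n_samples))
    for i in range(n_genes):
        rows[i] = _row_rng(seed, (0, i)).standard_normal(n_samples)
    df = pd.DataFrame(rows, index=_gene_ids(n_genes), columns=_sample_ids(n_samples))
    return ExpressionMatrix(df)


def _strata_indices(x3: np.ndarray, fraction: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lower / middle / upper sample indices by X3 rank."""
    n = x3.size
    k = int(math.floor(n * fraction))
    if k < 2:
        raise ValueError("stratum too small; need at least 2 samples per stratum")
    order = np.argsort(x3, kind="stable")
    return order[:k], order[k : n - k], order[n - k :]


def _correlated_pair(rng: np.random.Generator, n: int, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate standard normal sample with correlation rho."""
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    return a, rho * a + math.sqrt(max(0.0, 1.0 - rho * rho)) * b


def plant_switch_triplet(matrix: ExpressionMatrix, spec: TripletSpec, seed: int) -> ExpressionMatrix:
    """Overwrite the pair rows of ``spec`` with a cross-shaped pattern.

    The X3 row is untouched; the two pair rows are replaced by draws from the
    conditional bivariate-normal model (correlation ``rho_high`` in the upper
    X3-rank stratum, ``rho_low`` in the lower, 0 in the middle), plus
    ``driver_strength * X3`` when requested.
    """
    genes = matrix.values.index
    for gid in (spec.x3_id, *spec.pair_ids):
        if gid not in genes:
            raise KeyError(f"gene {gid!r} not in matrix")
    vals = matrix.values.copy()
    x3 = vals.loc[spec.x3_id].to_numpy(dtype=float)
    low, mid, high = _strata_indices(x3, spec.stratum_fraction)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))

    x1 = np.empty_like(x3)
    x2 = np.empty_like(x3)
    for idx, rho in ((high, spec.rho_high), (low, spec.rho_low), (mid, 0.0)):
        a, b = _correlated_pair(rng, idx.size, rho)
        x1[idx], x2[idx] = a, b
    if spec.driver_strength != 0.0:
        # centre/scale X3 before coupling so the driver term is comparable
        # across raw and transformed inputs
        z3 = (x3 - x3.mean()) / x3.std(ddof=1)
        x1 = x1 + spec.driver_strength * z3
        x2 = x2 + spec.driver_strength * z3
    vals.loc[spec.pair_ids[0]] = x1
    vals.loc[spec.pair_ids[1]] = x2
    return ExpressionMatrix(vals, matrix.sample_meta)


def generate_study(spec: StudySpec) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Generate a full study: null background + planted triplets + DEGs."""
    base = generate_null_matrix(spec.n_genes, spec.n_samples, spec.seed)
    groups = spec.groups or balanced_groups(spec.n_samples)
    meta = pd.DataFrame(
        [(sid, d, s) for sid, (d, s) in groups.items()],
        columns=["sample_id", "disease", "status"],
    ).set_index("sample_id")
    matrix = ExpressionMatrix(base.values * spec.noise_sd, meta)

    triplet_genes: set[str] = set()
    for i, tspec in enumerate(spec.triplets):
        matrix = plant_switch_triplet(matrix, tspec, seed=int(spec.seed) + 1 + i)
        triplet_genes |= {tspec.x3_id, *tspec.pair_ids}

    if spec.deg_ids:
        deg_ids = list(spec.deg_ids)
    else:
        free = [g for g in matrix.gene_ids if g not in triplet_genes]
        if spec.n_deg > len(free):
            raise ValueError("not enough free genes for the requested DEG count")
        deg_ids = free[: spec.n_deg]
    collisions = sorted(set(deg_ids) & triplet_genes)
    if collisions:
        warnings.warn(f"DEG/triplet gene collisions: {collisions}", stacklevel=2)

    case_cols = [sid for sid, (_, st) in groups.items() if st == "case"]
    vals = matrix.values
    if deg_ids and spec.deg_effect != 0.0:
        for gid in deg_ids:
            sd = vals.loc[gid].std(ddof=1)
            vals.loc[gid, case_cols] = vals.loc[gid, case_cols] + spec.deg_effect * sd
    truth = PlantedTruth(
        planted_triplets=list(spec.triplets),
        planted_degs=[(g, spec.deg_effect) for g in deg_ids],
        seed=spec.seed,
        collisions=collisions,
    )
    return ExpressionMatrix(vals, meta), truth


# -- truth serialization ---------------------------------------------------

def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    """Write the truth record as a TSV (one row per planted feature)."""
    rows = []
    for t in truth.planted_triplets:
        rows.append(
            {
                "kind": "triplet",
                "gene": t.x3_id,
                "partner1": t.pair_ids[0],
                "partner2": t.pair_ids[1],
                "rho_high": t.rho_high,
                "rho_low": t.rho_low,
                "stratum_fraction": t.stratum_fraction,
                "driver_strength": t.driver_strength,
            }
        )
    for gid, eff in truth.planted_degs:
        rows.append({"kind": "deg", "gene": gid, "rho_high": eff})
    df = pd.DataFrame(rows)
    df.attrs["seed"] = truth.seed
    with open(path, "w") as fh:
        fh.write(f"# seed={truth.seed}\n")
        if truth.collisions:
            fh.write(f"# collisions={','.join(truth.collisions)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_truth(path: str | Path) -> PlantedTruth:
    seed = 0
    collisions: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "seed":
                seed = int(val)
            elif key.strip() == "collisions" and val:
                collisions = val.split(",")
    df = pd.read_csv(path, sep="\t", comment="#")
    triplets = [
        TripletSpec(
            x3_id=str(r.gene),
            pair_ids=(str(r.partner1), str(r.partner2)),
            rho_high=float(r.rho_high),
            rho_low=float(r.rho_low),
            stratum_fraction=float(r.stratum_fraction),
            driver_strength=float(r.driver_strength),
        )
        for r in df[df["kind"] == "triplet"].itertuples()
    ]
    degs = [(str(r.gene), float(r.rho_high)) for r in df[df["kind"] == "deg"].itertuples()]
    return PlantedTruth(planted_triplets=triplets, planted_degs=degs, seed=seed, collisions=collisions)
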