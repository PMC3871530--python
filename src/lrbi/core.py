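"""Core domain types for the structural-equation view of a gene regulatory network.

The model couples steady-state expression to network structure and genetic
perturbations::

    Y = B Y + F X + E

where ``Y`` (m genes x N individuals) holds expression levels, ``B`` is the
directed regulatory-effect matrix (``B[i, j]`` is the effect of gene *j* on
gene *i*; zero diagonal, no self-loops), ``X`` (m x N) holds the genotype of
each gene's pre-assigned cis-eQTL, ``F`` is the diagonal matrix of eQTL
effect sizes and ``E`` is i.i.d. Gaussian measurement noise.

Because every unknown lives in one row of ``[B F]``, the system decomposes
exactly into m independent linear regressions — one per gene — with the other
genes' expression rows plus the gene's own genotype row as regressors.
:func:`build_row_regression` performs that decomposition;
:func:`generate_expression` runs the model forward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GRNModel",
    "Dataset",
    "RowRegression",
    "NoiseSpec",
    "CoefLabel",
    "build_row_regression",
    "generate_expression",
]

#: condition number above which (I - B) is treated as numerically singular
_COND_LIMIT = 1e8


@dataclass(frozen=True)
class CoefLabel:
    """Position label for one regression coefficient.

    ``kind`` is ``"B"`` for a regulatory effect (target, regulator) or ``"F"``
    for a cis-eQTL effect (gene, gene).
    """

    kind: str
    target: int
    regulator: int

    def __post_init__(self) -> None:
        if self.kind not in ("B", "F"):
            raise ValueError(f"label kind must be 'B' or 'F', got {self.kind!r}")
        if self.kind == "F" and self.target != self.regulator:
            raise ValueError("F labels are diagonal: target must equal regulator")
        if self.kind == "B" and self.target == self.regulator:
            raise ValueError("B labels exclude the diagonal (no self-loops)")


@dataclass(frozen=True)
class GRNModel:
    """True network: regulatory effects ``B`` and diagonal eQTL effects ``F``."""

    B: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        B = np.asarray(self.B, dtype=float)
        F = np.asarray(self.F, dtype=float)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "F", F)
        if B.ndim != 2 or B.shape[0] != B.shape[1]:
            raise ValueError(f"B must be square, got shape {B.shape}")
        if F.shape != B.shape:
            raise ValueError(f"F shape {F.shape} != B shape {B.shape}")
        if np.any(np.diag(B) != 0.0):
            raise ValueError("B must have an exactly zero diagonal (no self-loops)")
        if np.any(F[~np.eye(B.shape[0], dtype=bool)] != 0.0):
            raise ValueError("F must be diagonal (one cis-eQTL effect per gene)")

    @property
    def m(self) -> int:
        return self.B.shape[0]

    def edge_set(self) -> set[tuple[int, int]]:
        """Directed edges as (target, regulator) pairs with nonzero effect."""
        targets, regulators = np.nonzero(self.B)
        return set(zip(targets.tolist(), regulators.tolist()))


@dataclass(frozen=True)
class NoiseSpec:
    """I.i.d. Gaussian measurement noise with variance ``sigma2``."""

    sigma2: float

    def __post_init__(self) -> None:
        if not self.sigma2 > 0:
            raise ValueError(f"sigma2 must be > 0, got {self.sigma2}")


@dataclass(frozen=True)
class Dataset:
    """Aligned expression (``Y``) and genotype (``X``) matrices.

    Column *k* of both matrices refers to the same individual; row *i* of
    ``X`` is the genotype at gene *i*'s cis-eQTL.
    """

    Y: np.ndarray
    X: np.ndarray
    gene_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]
    genotype_codes: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self) -> None:
        Y = np.asarray(self.Y, dtype=float)
        X = np.asarray(self.X)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "X", X)
        if Y.ndim != 2:
            raise ValueError(f"Y must be 2-D, got ndim={Y.ndim}")
        if Y.shape != X.shape:
            raise ValueError(f"Y shape {Y.shape} != X shape {X.shape}")
        if self.gene_ids is None:
            object.__setattr__(
                self, "gene_ids", tuple(f"g{i + 1}" for i in range(Y.shape[0]))
            )
        else:
            object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if len(self.gene_ids) != Y.shape[0]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {Y.shape[0]} gene rows"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        codes = set(self.genotype_codes)
        if not set(np.unique(X).tolist()) <= codes:
            bad = sorted(set(np.unique(X).tolist()) - codes)
            raise ValueError(f"genotype entries {bad} outside code set {sorted(codes)}")

    @property
    def m(self) -> int:
        return self.Y.shape[0]

    @property
    def N(self) -> int:
        return self.Y.shape[1]

    def standardized(self) -> "Dataset":
        """Return a copy with each expression row z-scored across individuals."""
        mu = self.Y.mean(axis=1, keepdims=True)
        sd = self.Y.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return Dataset(
            (self.Y - mu) / sd, self.X, self.gene_ids, self.genotype_codes
        )


@dataclass(frozen=True)
class RowRegression:
    """One gene's regression problem.

    ``response`` is gene *i*'s expression row; ``design`` stacks the other
    genes' expression rows (ascending index, skipping *i*) and, last, gene
    *i*'s genotype row. ``coef_labels`` maps coefficient positions back to
    entries of ``B`` and ``F``.
    """

    gene_index: int
    response: np.ndarray
    design: np.ndarray
    coef_labels: tuple[CoefLabel, ...]

    def __post_init__(self) -> None:
        if self.design.ndim != 2:
            raise ValueError("design must be 2-D")
        if self.design.shape[1] != self.response.shape[0]:
            raise ValueError("design columns must match response length")
        if len(self.coef_labels) != self.design.shape[0]:
            raise ValueError("one label per design row required")
        f_positions = [k for k, lab in enumerate(self.coef_labels) if lab.kind == "F"]
        if f_positions != [len(self.coef_labels) - 1]:
            raise ValueError("exactly one F label, in the last position, required")

    @property
    def n_coef(self) -> int:
        return self.design.shape[0]

    @property
    def N(self) -> int:
        return self.response.shape[0]


def build_row_regression(dataset: Dataset, gene_index: int) -> RowRegression:
    """Extract gene ``gene_index``'s linear regression from the full system.

    The response is row *i* of ``Y``; regressors are all other expression rows
    in ascending gene order followed by row *i* of ``X``. The coefficient
    vector therefore targets ``B[i, j]`` for ``j != i`` and, last, ``F[i, i]``.

    Raises
    ------
    IndexError
        if ``gene_index`` is outside ``[0, m)``.
    ValueError
        if the dataset has fewer than two genes (no regressors besides the
        genotype row would remain).
    """
    m = dataset.m
    if m < 2:
        raise ValueError(f"need at least 2 genes to form a regression, got m={m}")
    if not 0 <= gene_index < m:
        raise IndexError(f"gene_index {gene_index} out of range [0, {m})")

    others = [j for j in range(m) if j != gene_index]
    design = np.vstack([dataset.Y[others, :], dataset.X[gene_index, :][None, :]])
    design = np.asarray(design, dtype=float)
    labels = tuple(
        CoefLabel("B", gene_index, j) for j in others
    ) + (CoefLabel("F", gene_index, gene_index),)
    return RowRegression(
        gene_index=gene_index,
        response=dataset.Y[gene_index, :].copy(),
        design=design,
        coef_labels=labels,
    )


def generate_expression(
    model: GRNModel,
    X: np.ndarray,
    noise: NoiseSpec,
    seed: int | np.random.SeedSequence | np.random.Generator,
    genotype_codes: tuple[int, ...] = (0, 1, 2),
) -> Dataset:
    """Run the structural model forward: solve ``Y = B Y + F X + E`` for ``Y``.

    ``E`` is i.i.d. Normal(0, sigma2); the solve is ``Y = (I - B)^{-1}(F X + E)``,
    valid for cyclic as well as acyclic networks provided ``I - B`` is well
    conditioned. Deterministic given ``seed``.
    """
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[0] != model.m:
        raise ValueError(f"X must be {model.m} x N, got shape {X.shape}")
    A = np.eye(model.m) - model.B
    if np.linalg.cond(A) > _COND_LIMIT:
        raise ValueError(
            "unstable network: condition number of (I - B) exceeds "
            f"{_COND_LIMIT:g}"
        )
    rng = np.random.default_rng(seed)
    E = rng.normal(0.0, np.sqrt(noise.sigma2), size=X.shape)
    Y = np.linalg.solve(A, model.F @ X + E)
    return Dataset(Y=Y, X=X, genotype_codes=genotype_codes)
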