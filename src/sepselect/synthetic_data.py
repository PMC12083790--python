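"""Synthetic expression matrices with planted informative genes.

The generator emulates the statistical shape of a curated leukemia
microarray study: n = 64 samples in 5 unbalanced classes (8/10/26/10/10),
thousands of gene probes, and a small planted set of informative genes.
A background gene is class-independent Gaussian noise N(0, sigma_bg^2).
An informative gene in class j is N(j * delta, sigma_inf^2) with
sigma_inf > sigma_bg, so planted genes carry both between-class mean shifts
(classifiers can exploit them) and larger within-class spread than
background (the descending separability score ranks them first).  Class
means sit on the monotone ladder j * delta rather than random directions so
linear one-hot classification stays well-posed and failures are
interpretable.

Not modelled: probe-level intensity distributions, batch effects,
gene–gene correlation, heavy tails — conclusions drawn here are about the
pipeline's mechanics, not about any real accession.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .io_expression import ClassMap, ExpressionMatrix

__all__ = ["SimulationConfig", "simulate", "fixture_small"]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults mirror the study's class structure.

    n_per_class
        Samples per class (default 8/10/26/10/10, total 64).
    p
        Total genes (default 2000; large enough for the p >> n regime while
        keeping simulations fast — a full-scale 22283-gene matrix is one
        constructor call away).
    n_informative
        Number of planted informative genes (default 20).
    delta
        Between-class mean separation: class j has mean j * delta on an
        informative gene (default 5.0, intensity units).
    sigma_informative
        Within-class sd of informative genes (default 1.0).
    sigma_background
        Sd of background genes (default 0.1; mean 0).
    """

    n_per_class: tuple[int, ...] = (8, 10, 26, 10, 10)
    p: int = 2000
    n_informative: int = 20
    delta: float = 5.0
    sigma_informative: float = 1.0
    sigma_background: float = 0.1
    seed: int = 0
    class_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.n_per_class) < 2:
            raise DomainError("need at least 2 classes")
        if any(n < 1 for n in self.n_per_class):
            raise DomainError("class sizes must be positive")
        if self.p < 1:
            raise DomainError("p must be positive")
        if not 0 <= self.n_informative <= self.p:
            raise DomainError("n_informative must be in [0, p]")
        if self.sigma_informative <= 0 or self.sigma_background <= 0:
            raise DomainError("sigma values must be > 0")
        if self.class_names is not None and len(self.class_names) != len(self.n_per_class):
            raise DomainError("class_names length must match n_per_class")

    @property
    def n_samples(self) -> int:
        return sum(self.n_per_class)

    @property
    def n_classes(self) -> int:
        return len(self.n_per_class)


def simulate(config: SimulationConfig) -> tuple[ExpressionMatrix, np.ndarray]:
    """Draw one matrix from ``config``; returns (matrix, planted gene indices).

    Deterministic per seed.  Planted indices are drawn without replacement,
    returned sorted, and are the ground truth for recovery experiments.
    """
    rng = np.random.default_rng(config.seed)
    n, p, c = config.n_samples, config.p, config.n_classes

    names = config.class_names or tuple(f"Class_{j}" for j in range(1, c + 1))
    class_map = ClassMap(names)
    labels = np.concatenate(
        [np.repeat(name, sz) for name, sz in zip(names, config.n_per_class)]
    )
    codes = np.concatenate(
        [np.repeat(j + 1, sz) for j, sz in enumerate(config.n_per_class)]
    )

    planted = np.sort(rng.choice(p, size=config.n_informative, replace=False))
    values = rng.normal(0.0, config.sigma_background, size=(n, p))
    if config.n_informative:
        means = (codes[:, None].astype(float) * config.delta)  # class j -> j*delta
        values[:, planted] = rng.normal(
            means, config.sigma_informative, size=(n, config.n_informative)
        )

    width = len(str(p))
    matrix = ExpressionMatrix(
        values=values,
        sample_ids=[f"S{i + 1}" for i in range(n)],
        gene_ids=[f"G{j:0{width}d}" for j in range(p)],
        labels=labels,
        class_map=class_map,
    )
    return matrix, planted


# Hand-checked 6-sample x 4-gene anchor fixture, 2 classes (A: rows 0-2,
# B: rows 3-5).  Per gene: class means, max |deviation| per class, score
# d = min of the two maxima:
#   g1  A: 1,2,3   (mean 2,  max dev 1)   B: 10,10,13 (mean 11, max dev 2)  d = 1
#   g2  A: 0,0,0   (mean 0,  max dev 0)   B: 5,6,7    (mean 6,  max dev 1)  d = 0
#   g3  A: 2,4,9   (mean 5,  max dev 4)   B: 1,5,9    (mean 5,  max dev 4)  d = 4
#   g4  A: 1,1,4   (mean 2,  max dev 2)   B: 0,3,3    (mean 2,  max dev 2)  d = 2
# scores [1, 0, 4, 2]; descending ranking [2, 3, 0, 1].
_FIXTURE_VALUES = np.array(
    [
        [1.0, 0.0, 2.0, 1.0],
        [2.0, 0.0, 4.0, 1.0],
        [3.0, 0.0, 9.0, 4.0],
        [10.0, 5.0, 1.0, 0.0],
        [10.0, 6.0, 5.0, 3.0],
        [13.0, 7.0, 9.0, 3.0],
    ]
)

FIXTURE_SCORES = np.array([1.0, 0.0, 4.0, 2.0])
FIXTURE_RANKING = np.array([2, 3, 0, 1])


def fixture_small() -> ExpressionMatrix:
    """The fixed 6x4 two-class anchor matrix documented above."""
    return ExpressionMatrix(
        values=_FIXTURE_VALUES.copy(),
        sample_ids=[f"S{i + 1}" for i in range(6)],
        gene_ids=["g1", "g2", "g3", "g4"],
        labels=np.array(["A"] * 3 + ["B"] * 3, dtype=object),
        class_map=ClassMap(("A", "B")),
    )
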