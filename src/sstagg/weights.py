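"""Effective nodal weights S_{n->REF}: the continuous relaxation of nodal signs.

On a balanced graph every spanning tree assigns a node the same path sign, so
S_{n->REF} collapses to the rigid sign s_{n->REF} in {-1,+1}.  On an
unbalanced graph S_{n->REF} in [-1,+1] is the average of the path sign over
(all, or a sampled subset of) spanning trees and quantifies how unambiguously
a node is related to the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

import numpy as np


@dataclass
class EffectiveWeights:
    """Per-node effective weights with their positive/negative visit counts.

    ``n_plus[n] + n_minus[n] == n_trees_total`` for every node: each tree
    (equivalently each walker) assigns each node exactly one sign.  ``exact``
    marks weights obtained by exhaustive enumeration rather than sampling;
    for exact weights ``exact_values`` carries the underlying rationals.
    """

    weights: dict[str, float]
    n_plus: dict[str, int]
    n_minus: dict[str, int]
    n_trees_total: int
    exact: bool = False
    stderr: dict[str, float] = field(default_factory=dict)
    exact_values: dict[str, Fraction] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for n, w in self.weights.items():
            if not -1.0 <= w <= 1.0:
                raise ValueError(f"effective weight of {n!r} outside [-1,1]: {w}")
            if self.n_plus[n] + self.n_minus[n] != self.n_trees_total:
                raise ValueError(
                    f"count conservation violated at {n!r}: "
                    f"{self.n_plus[n]} + {self.n_minus[n]} != {self.n_trees_total}"
                )

    def __getitem__(self, node: str) -> float:
        return self.weights[node]

    def __iter__(self):
        return iter(self.weights)

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.weights)

    def to_frame(self):
        """Tabular view: node, S, N_plus, N_minus, SE."""
        import pandas as pd

        return pd.DataFrame(
            {
                "node": list(self.weights),
                "S": [self.weights[n] for n in self.weights],
                "N_plus": [self.n_plus[n] for n in self.weights],
                "N_minus": [self.n_minus[n] for n in self.weights],
                "SE": [self.stderr.get(n, 0.0) for n in self.weights],
            }
        )

    @classmethod
    def from_sign_counts(
        cls,
        n_plus: Mapping[str, int],
        n_minus: Mapping[str, int],
        exact: bool = False,
        exact_values: Mapping[str, Fraction] | None = None,
    ) -> "EffectiveWeights":
        """Build weights from visit counts: S_n = (N+ - N-) / (N+ + N-).

        Sampled weights get the binomial standard error
        ``sqrt((1 - S_n^2) / N)`` of the sign-average estimator.
        """
        nodes = list(n_plus)
        total = n_plus[nodes[0]] + n_minus[nodes[0]]
        weights = {
            n: (n_plus[n] - n_minus[n]) / total for n in nodes
        }
        stderr = {}
        if not exact:
            stderr = {
                n: float(np.sqrt(max(0.0, 1.0 - weights[n] ** 2) / total))
                for n in nodes
            }
        return cls(
            weights=weights,
            n_plus=dict(n_plus),
            n_minus=dict(n_minus),
            n_trees_total=total,
            exact=exact,
            stderr=stderr,
            exact_values=dict(exact_values or {}),
        )
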