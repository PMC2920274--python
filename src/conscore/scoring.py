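"""Method registry and whole-alignment scoring.

The registry maps canonical method names (wu70, shannon, karlin96, ...)
to scoring routines.  All values reported by :func:`score_alignment` are
in *conservation orientation*: methods whose native formulation scores
variability (wu70, taylor86, shannon(w), mirny99, caffrey04w,
thompson97, mihalek04, zhang08) are negated at this boundary; ``raw=True``
recovers the native values.

The three Shannon-entropy variants of the literature (Sander91, Shenkin91,
Gerstein95) are monotone transforms of one another within an alignment and
are exposed as the single method ``shannon`` (plus the sequence-weighted
``shannonw``).  The optional external Rate4Site adapter adds ``mayrose04``
when an executable is supplied; otherwise the registry holds 23 methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .alphabet import N_AA
from .matrices import (
    ScoreMatrixSet,
    column_distribution,
    default_matrices,
    distance_matrix,
    henikoff_weights,
)
from .msa_io import Alignment, AlignmentInputError, Column, SiteAnnotation, analyzable_columns
from .properties import PropertySets, default_properties
from .scores import entropy, frequency, matrix as matscores, phylogeny, property as propscores
from scipy.stats import binom


@dataclass
class AlignmentContext:
    """Per-alignment precomputations shared by all scoring methods."""

    alignment: Alignment
    annotations: Sequence[SiteAnnotation] = ()
    matrices: ScoreMatrixSet = field(default_factory=default_matrices)
    properties: PropertySets = field(default_factory=default_properties)

    @cached_property
    def columns(self) -> list[Column]:
        cols = analyzable_columns(self.alignment, self.annotations)
        if not cols:
            raise AlignmentInputError(
                f"alignment {self.alignment.id!r} has no analyzable columns"
            )
        return cols

    @cached_property
    def codes(self) -> np.ndarray:
        """(n_cols, N) integer residue codes of the analyzable columns."""
        return np.stack([c.codes for c in self.columns])

    @cached_property
    def weights(self) -> np.ndarray:
        return henikoff_weights(self.alignment)

    @cached_property
    def distances(self) -> np.ndarray:
        return distance_matrix(self.alignment)

    @cached_property
    def tree(self) -> phylogeny.UpgmaTree:
        return phylogeny.build_upgma(self.distances)

    @cached_property
    def p_unweighted(self) -> np.ndarray:
        """(n_cols, 20) unweighted residue distributions."""
        n = self.alignment.n_sequences
        out = np.zeros((len(self.columns), N_AA))
        rows = np.repeat(np.arange(len(self.columns)), n)
        np.add.at(out, (rows, self.codes.ravel()), 1.0 / n)
        return out

    @cached_property
    def p_weighted(self) -> np.ndarray:
        """(n_cols, 20) Henikoff-weighted residue distributions."""
        w = np.tile(self.weights, len(self.columns))
        out = np.zeros((len(self.columns), N_AA))
        rows = np.repeat(np.arange(len(self.columns)), self.alignment.n_sequences)
        np.add.at(out, (rows, self.codes.ravel()), w)
        return out

    @cached_property
    def alignment_distribution(self) -> np.ndarray:
        """Pooled unweighted residue distribution over analyzable columns."""
        return self.p_unweighted.mean(axis=0)


# ---------------------------------------------------------------------------
# vectorized per-alignment score computations (raw orientation)


def _per_column(fn: Callable[[np.ndarray], float]) -> Callable[[AlignmentContext], np.ndarray]:
    def compute(ctx: AlignmentContext) -> np.ndarray:
        return np.array([fn(codes) for codes in ctx.codes])

    return compute


def _lockless99(ctx: AlignmentContext) -> np.ndarray:
    n = ctx.alignment.n_sequences
    q = ctx.matrices.q
    counts = np.rint(ctx.p_unweighted * n).astype(int)
    log_obs = binom.logpmf(counts, n, q[None, :])
    log_exp = binom.logpmf(np.rint(n * q).astype(int), n, q)
    return np.sqrt(((log_obs - log_exp[None, :]) ** 2).sum(axis=1))


def _evolutionary_trace(
    ctx: AlignmentContext, group_entropy: Callable[[np.ndarray], float]
) -> np.ndarray:
    """Shared trace summation: aggregate group counts up the UPGMA tree."""
    tree = ctx.tree
    sets, coeffs = tree.cut_coefficients()
    n_cols = len(ctx.columns)
    totals = np.zeros(n_cols)
    for members, c in zip(sets, coeffs):
        if c == 0.0 or len(members) == 1:
            continue
        idx = sorted(members)
        sub = ctx.codes[:, idx]
        counts = np.zeros((n_cols, N_AA))
        rows = np.repeat(np.arange(n_cols), len(idx))
        np.add.at(counts, (rows, sub.ravel()), 1.0)
        p = counts / len(idx)
        totals += c * np.apply_along_axis(group_entropy, 1, p)
    return totals


def _mihalek04(ctx: AlignmentContext) -> np.ndarray:
    return _evolutionary_trace(ctx, lambda p: entropy.shannon_entropy(p, base=np.e))


def _zhang08(ctx: AlignmentContext) -> np.ndarray:
    M_f = ctx.matrices.M_f
    return _evolutionary_trace(
        ctx, lambda p: entropy.von_neumann_entropy(p, M_f, base=np.e)
    )


@dataclass(frozen=True)
class Method:
    """A registered scoring method."""

    name: str
    family: str
    variability: bool  # native orientation scores variability -> negate on output
    compute: Callable[[AlignmentContext], np.ndarray]


def build_registry(rate4site_exe: str | None = None) -> dict[str, Method]:
    """Construct the method registry in canonical order."""

    def m(name, family, variability, compute):
        return Method(name, family, variability, compute)

    methods = [
        m("wu70", "frequency", True, _per_column(frequency.wu70)),
        m("lockless99", "frequency", False, _lockless99),
        m(
            "pei01var",
            "frequency",
            False,
            lambda ctx: np.array(
                [frequency.pei01var(p, ctx.matrices.q) for p in ctx.p_unweighted]
            ),
        ),
        m(
            "pei01varw",
            "frequency",
            False,
            lambda ctx: np.array(
                [frequency.pei01var(p, ctx.matrices.q) for p in ctx.p_weighted]
            ),
        ),
        m(
            "taylor86",
            "property",
            True,
            lambda ctx: np.array(
                [propscores.taylor86(c, ctx.properties) for c in ctx.codes], dtype=float
            ),
        ),
        m(
            "zvelebil87",
            "property",
            False,
            lambda ctx: np.array(
                [propscores.zvelebil87(c, ctx.properties) for c in ctx.codes]
            ),
        ),
        m(
            "shannon",
            "entropy",
            True,
            lambda ctx: np.array([entropy.shannon(p) for p in ctx.p_unweighted]),
        ),
        m(
            "shannonw",
            "entropy",
            True,
            lambda ctx: np.array([entropy.shannon(p) for p in ctx.p_weighted]),
        ),
        m(
            "wang06w",
            "entropy",
            False,
            lambda ctx: np.array(
                [entropy.wang06w(p, ctx.matrices.q) for p in ctx.p_weighted]
            ),
        ),
        m(
            "capra07w",
            "entropy",
            False,
            lambda ctx: np.array(
                [entropy.capra07w(p, ctx.matrices.q) for p in ctx.p_weighted]
            ),
        ),
        m(
            "mirny99",
            "grouped-entropy",
            True,
            lambda ctx: np.array([entropy.mirny99(p) for p in ctx.p_unweighted]),
        ),
        m(
            "williamson95",
            "grouped-entropy",
            False,
            lambda ctx: np.array(
                [
                    entropy.williamson95(p, ctx.alignment_distribution)
                    for p in ctx.p_unweighted
                ]
            ),
        ),
        m(
            "caffrey04w",
            "entropy",
            True,
            lambda ctx: np.array(
                [entropy.caffrey04w(p, ctx.matrices.M_f) for p in ctx.p_weighted]
            ),
        ),
        m(
            "sander91sp",
            "matrix",
            False,
            lambda ctx: (
                lambda pw: np.array(
                    [
                        matscores.sander91sp(c, ctx.matrices.M_K, pw)
                        for c in ctx.codes
                    ]
                )
            )(matscores.sander91sp_pair_weights(ctx.distances)),
        ),
        m(
            "karlin96",
            "matrix",
            False,
            lambda ctx: np.array(
                [matscores.karlin96(c, ctx.matrices.M_K) for c in ctx.codes]
            ),
        ),
        m(
            "valdar01",
            "matrix",
            False,
            lambda ctx: (
                lambda w: np.array(
                    [matscores.valdar01(c, ctx.matrices.M_V, w) for c in ctx.codes]
                )
            )(matscores.valdar_weights(ctx.distances)),
        ),
        m(
            "pei01sp",
            "matrix",
            False,
            lambda ctx: np.array(
                [matscores.pei01sp(p, ctx.matrices.M_K) for p in ctx.p_unweighted]
            ),
        ),
        m(
            "pei01spw",
            "matrix",
            False,
            lambda ctx: np.array(
                [matscores.pei01sp(p, ctx.matrices.M_K) for p in ctx.p_weighted]
            ),
        ),
        m(
            "thompson97",
            "matrix",
            True,
            lambda ctx: np.array(
                [
                    matscores.thompson97(c, ctx.matrices.M, ctx.weights)
                    for c in ctx.codes
                ]
            ),
        ),
        m(
            "mihalek07",
            "matrix",
            False,
            lambda ctx: np.array(
                [matscores.mihalek07(c, ctx.matrices.M_M) for c in ctx.codes]
            ),
        ),
        m(
            "liu08w",
            "matrix",
            False,
            lambda ctx: np.array(
                [matscores.liu08w(c, ctx.matrices.M_L, ctx.weights) for c in ctx.codes]
            ),
        ),
        m("mihalek04", "phylogeny", True, _mihalek04),
        m("zhang08", "phylogeny", True, _zhang08),
    ]
    registry = {mm.name: mm for mm in methods}
    if rate4site_exe is not None:

        def _mayrose(ctx: AlignmentContext) -> np.ndarray:
            rates = phylogeny.mayrose04_adapter(ctx.alignment, rate4site_exe)
            if rates is None:
                raise AlignmentInputError("Rate4Site adapter produced no output")
            # external tool reports one rate per alignment site; keep analyzable ones
            return np.array([rates[c.index - 1] for c in ctx.columns])

        registry["mayrose04"] = Method("mayrose04", "phylogeny", True, _mayrose)
    return registry


DEFAULT_REGISTRY = build_registry()


def score_alignment(
    alignment: Alignment,
    annotations: Sequence[SiteAnnotation] = (),
    methods: Sequence[str] | None = None,
    matrices: ScoreMatrixSet | None = None,
    properties: PropertySets | None = None,
    registry: dict[str, Method] | None = None,
    raw: bool = False,
) -> pd.DataFrame:
    """Score every analyzable column of an alignment with every method.

    Returns a DataFrame with columns ``alignment_id``, ``column`` (1-based
    source index), ``is_catalytic`` and one column per method.  Values are
    conservation-oriented unless ``raw=True``.
    """
    registry = registry or DEFAULT_REGISTRY
    names = list(methods) if methods is not None else list(registry)
    unknown = [n for n in names if n not in registry]
    if unknown:
        raise KeyError(
            f"unknown methods {unknown}; available: {sorted(registry)}"
        )
    ctx = AlignmentContext(
        alignment=alignment,
        annotations=annotations,
        matrices=matrices or default_matrices(),
        properties=properties or default_properties(),
    )
    data = {
        "alignment_id": [c.alignment_id for c in ctx.columns],
        "column": [c.index for c in ctx.columns],
        "is_catalytic": [c.is_catalytic for c in ctx.columns],
    }
    for name in names:
        method = registry[name]
        values = np.asarray(method.compute(ctx), dtype=float)
        data[name] = -values if (method.variability and not raw) else values
    return pd.DataFrame(data)


def score_collection(
    alignments: Sequence[Alignment],
    annotations: Sequence[SiteAnnotation] = (),
    **kwargs,
) -> pd.DataFrame:
    """Concatenate :func:`score_alignment` over a collection."""
    frames = [score_alignment(a, annotations, **kwargs) for a in alignments]
    return pd.concat(frames, ignore_index=True)
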