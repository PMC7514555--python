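"""Censoring schemes and generation of progressive first-failure censored samples.

A progressive first-failure (PFF) experiment places ``n`` groups of ``k``
identical units on test.  At the *i*-th observed group-minimum failure, the
failing group and ``R[i]`` further surviving groups are withdrawn; the
experiment stops at the ``m``-th failure.  ``k = 1`` reduces to progressive
Type-II censoring, ``R = 0`` to first-failure censoring, and
``k = 1, R = (0, ..., 0, n-m)`` to conventional Type-II censoring.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .distribution import IWDParams, quantile

__all__ = ["CensoringScheme", "PFFSample", "expand_shorthand", "parse_scheme", "simulate_pff"]


class SchemeError(ValueError):
    """Raised for malformed or inconsistent censoring-scheme descriptors."""


@dataclass(frozen=True)
class CensoringScheme:
    """Progressive first-failure censoring scheme ``(k, n, m, R)``.

    ``sum(R) = n - m`` must hold so that every group is accounted for;
    the total number of units on test is ``N = k * n``.
    """

    k: int
    n: int
    R: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.k < 1:
            raise SchemeError(f"group size k must be >= 1, got {self.k}")
        if self.n < 1:
            raise SchemeError(f"group count n must be >= 1, got {self.n}")
        R = tuple(int(r) for r in self.R)
        object.__setattr__(self, "R", R)
        if len(R) < 1 or len(R) > self.n:
            raise SchemeError(f"m = len(R) = {len(R)} must satisfy 1 <= m <= n = {self.n}")
        if any(r < 0 for r in R):
            raise SchemeError("removal counts must be non-negative")
        if sum(R) != self.n - len(R):
            raise SchemeError(
                f"sum(R) = {sum(R)} does not equal n - m = {self.n - len(R)}"
            )

    @property
    def m(self) -> int:
        """Number of observed failures."""
        return len(self.R)

    @property
    def N(self) -> int:
        """Total units on test, ``k * n``."""
        return self.k * self.n


@dataclass(frozen=True)
class PFFSample:
    """An ordered PFF-censored sample tied to its censoring scheme."""

    scheme: CensoringScheme
    times: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or len(t) != self.scheme.m:
            raise ValueError(
                f"sample has {len(t)} times but scheme expects m = {self.scheme.m}"
            )
        if np.any(t <= 0) or np.any(~np.isfinite(t)):
            raise ValueError("failure times must be strictly positive and finite")
        if np.any(np.diff(t) < 0):
            raise ValueError("failure times must be non-decreasing")

    @property
    def m(self) -> int:
        return self.scheme.m


_TOKEN = re.compile(r"\s*(\(|\)|\*|,|\d+)")


def _tokenize(text: str) -> list[str]:
    out, pos = [], 0
    while pos < len(text):
        mobj = _TOKEN.match(text, pos)
        if mobj is None:
            if text[pos:].strip() == "":
                break
            raise SchemeError(f"unexpected character at position {pos} in {text!r}")
        out.append(mobj.group(1))
        pos = mobj.end()
    return out


def expand_shorthand(text: str) -> tuple[int, ...]:
    """Expand a star-shorthand removal vector into an explicit tuple.

    Grammar: ``a*b`` repeats the value ``a`` ``b`` times, ``(...)*b`` repeats
    a parenthesised list, and commas concatenate.  ``(0*5)`` expands to
    ``(0, 0, 0, 0, 0)`` and ``((1,0)*2)`` to ``(1, 0, 1, 0)``.
    """
    tokens = _tokenize(text)
    pos = 0

    def parse_list(depth: int) -> list[int]:
        nonlocal pos
        items: list[int] = []
        expect_item = True
        while pos < len(tokens):
            tok = tokens[pos]
            if tok == ")":
                if depth == 0:
                    raise SchemeError(f"unbalanced ')' in {text!r}")
                break
            if tok == ",":
                if expect_item:
                    raise SchemeError(f"empty term in {text!r}")
                pos += 1
                expect_item = True
                continue
            if not expect_item:
                raise SchemeError(f"missing ',' before {tok!r} in {text!r}")
            if tok == "(":
                pos += 1
                inner = parse_list(depth + 1)
                if pos >= len(tokens) or tokens[pos] != ")":
                    raise SchemeError(f"unbalanced '(' in {text!r}")
                pos += 1
                items.extend(inner * _maybe_repeat())
            else:
                try:
                    val = int(tok)
                except ValueError:
                    raise SchemeError(f"bad token {tok!r} in {text!r}") from None
                pos += 1
                items.extend([val] * _maybe_repeat())
            expect_item = False
        return items

    def _maybe_repeat() -> int:
        nonlocal pos
        if pos < len(tokens) and tokens[pos] == "*":
            pos += 1
            if pos >= len(tokens) or not tokens[pos].isdigit():
                raise SchemeError(f"'*' must be followed by a count in {text!r}")
            count = int(tokens[pos])
            pos += 1
            return count
        return 1

    result = parse_list(0)
    if pos != len(tokens):
        raise SchemeError(f"trailing tokens in {text!r}")
    if not result:
        raise SchemeError(f"empty scheme {text!r}")
    return tuple(result)


def parse_scheme(text: str, k: int, n: int) -> CensoringScheme:
    """Parse a star-shorthand removal vector into a validated scheme.

    Raises :class:`SchemeError` if the text is malformed or if the expanded
    vector is inconsistent with ``n`` (``sum(R) != n - m``).
    """
    return CensoringScheme(k=k, n=n, R=expand_shorthand(text))


def simulate_pff(scheme: CensoringScheme, p: IWDParams, seed) -> PFFSample:
    """Generate one PFF-censored sample from the inverse Weibull law.

    Uses the uniform-spacings construction for progressive Type-II order
    statistics: with ``W_i`` i.i.d. uniform,
    ``V_i = W_i**(1/(i + R_m + ... + R_{m-i+1}))`` and
    ``U_i = 1 - V_m V_{m-1} ... V_{m-i+1}`` are progressive Type-II uniform
    order statistics.  A PFF sample from ``F`` is a progressive Type-II
    sample from the first-failure law ``1 - (1-F)**k``, so
    ``X_i = F^{-1}(1 - (1-U_i)**(1/k))``.

    ``seed`` may be an int or any :func:`numpy.random.default_rng` seed;
    identical seeds reproduce the sample bitwise.
    """
    rng = np.random.default_rng(seed)
    R = np.asarray(scheme.R)
    m = scheme.m
    W = rng.uniform(size=m)
    # exponent for V_i: i + R_m + R_{m-1} + ... + R_{m-i+1}
    denom = np.arange(1, m + 1) + np.cumsum(R[::-1])
    V = W ** (1.0 / denom)
    U = 1.0 - np.cumprod(V[::-1])
    # invert through the first-failure CDF 1-(1-F)^k, stably for U near 1
    Fvals = -np.expm1(np.log1p(-U) / scheme.k)
    times = np.sort(quantile(Fvals, p))
    return PFFSample(scheme=scheme, times=times)
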