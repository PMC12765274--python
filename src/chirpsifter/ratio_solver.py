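"""Pulse-length-ratio solver for chirp refocusing conditions.

A chirped pi/2 pulse tips spins at different offsets at different times and
so imprints a parabolic phase roll across its excitation band.  For a train
of chirp pulses sharing one sweep width, the roll is refocused for a given
coherence-order pathway when the pulse lengths and sweep directions satisfy
the linear condition

    sum_i  s_i * tp_i * (o-_i - o+_i)  =  0,

where ``s_i`` is +1 for an up sweep and -1 for a down sweep, ``tp_i`` the
pulse length, and ``o-_i`` / ``o+_i`` the coherence order before/after pulse
``i``.  With several pathways (or extra conditions such as dispersion
matching) this becomes a small homogeneous linear system; physically
meaningful solutions are the strictly positive rays of its nullspace.

Everything here is exact: lengths are ``fractions.Fraction`` and the system
is solved with rational Gaussian elimination, so every reported solution has
a residual of exactly zero for every pathway.

Selection among under-determined families
-----------------------------------------
Many constraint sets leave a free parameter.  The solver then reports the
smallest primitive positive-integer solution, preferring solutions in which
every pi-role pulse is strictly longer than every pi/2-role pulse (pi pulses
need a much higher amplitude, so at a given amplifier limit they should take
the longer relative lengths), then ranking by total length.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd
from typing import Iterable, Sequence

import sympy

__all__ = [
    "CoherencePathway",
    "RatioSolution",
    "InfeasibleResult",
    "eq_residual",
    "solid_echo_pathway",
    "dispersion_match_pathway",
    "solve_ratios",
    "enumerate_patterns",
    "verify_dual_refocusing",
]


@dataclass(frozen=True)
class CoherencePathway:
    """Coherence orders (before, after) for each pulse of a sequence."""

    orders: tuple[tuple[int, int], ...]
    max_order: int = 1

    def __post_init__(self) -> None:
        for o_minus, o_plus in self.orders:
            if abs(o_minus) > self.max_order or abs(o_plus) > self.max_order:
                raise ValueError(
                    f"coherence orders {(o_minus, o_plus)} exceed the "
                    f"single-quantum bound {self.max_order}"
                )

    def __len__(self) -> int:
        return len(self.orders)

    @classmethod
    def from_orders(cls, orders: Sequence[int], **kw) -> "CoherencePathway":
        """Build from the order in each interval, e.g. [0, 1, -1] for a
        two-pulse echo 0 -> +1 -> -1."""
        pairs = tuple(
            (orders[i], orders[i + 1]) for i in range(len(orders) - 1)
        )
        return cls(pairs, **kw)

    @classmethod
    def parse(cls, text: str, **kw) -> "CoherencePathway":
        """Parse ``"0,1;1,-1;..."`` into per-pulse (before, after) pairs."""
        pairs = []
        for chunk in text.split(";"):
            a, b = chunk.split(",")
            pairs.append((int(a), int(b)))
        return cls(tuple(pairs), **kw)

    def coefficients(self, signs: Sequence[int]) -> tuple[int, ...]:
        """Row of the constraint matrix: ``s_i * (o-_i - o+_i)``."""
        if len(signs) != len(self.orders):
            raise ValueError(
                f"{len(signs)} signs for a pathway over {len(self.orders)} pulses"
            )
        return tuple(
            s * (om - op) for s, (om, op) in zip(signs, self.orders)
        )


def solid_echo_pathway(n_pulses: int, first: int = 0, second: int = 2) -> CoherencePathway:
    """Pathway encoding dipolar refocusing by the two pi/2 pulses alone.

    Pulse ``first`` excites (0 -> +1), pulse ``second`` inverts (+1 -> -1),
    all other pulses are spectators (no order change).  Its residual being
    zero makes the solid echo refocus the dipolar coupling without offset
    dispersion (e.g. the 2:1 first-to-third length relation for up sweeps).
    """
    orders = []
    for i in range(n_pulses):
        if i == first:
            orders.append((0, 1))
        elif i == second:
            orders.append((1, -1))
        elif i < first:
            orders.append((0, 0))
        elif i < second:
            orders.append((1, 1))
        else:
            orders.append((-1, -1))
    return CoherencePathway(tuple(orders))


def dispersion_match_pathway(
    n_pulses: int, echo: tuple[int, int] = (0, 1), target: int = 2
) -> CoherencePathway:
    """Constraint that the echo of pulses ``echo`` arrives at pulse ``target``
    with the same offset-time dispersion that ``target`` itself imprints.

    This is the condition under which the third SIFTER pulse does not affect
    the in-phase coherence: each offset's echo forms exactly when the third
    pulse sweeps past that offset.  Encoded as a pseudo-pathway whose
    residual is ``-s_a*tp_a + 2*s_b*tp_b - s_c*tp_c``.
    """
    a, b = echo
    orders = []
    for i in range(n_pulses):
        if i == a:
            orders.append((0, 1))
        elif i == b:
            orders.append((1, -1))
        elif i == target:
            orders.append((0, 1))
        else:
            orders.append((0, 0))
    return CoherencePathway(tuple(orders))


def eq_residual(
    lengths: Sequence, signs: Sequence[int], pathway: CoherencePathway
) -> Fraction:
    """Refocusing residual ``sum_i s_i*tp_i*(o-_i - o+_i)``; exact for
    rational lengths."""
    if len(lengths) != len(signs) or len(lengths) != len(pathway):
        raise ValueError(
            f"lengths ({len(lengths)}), signs ({len(signs)}) and pathway "
            f"({len(pathway)}) must all have the same number of pulses"
        )
    coeffs = pathway.coefficients(signs)
    total = Fraction(0)
    for c, t in zip(coeffs, lengths):
        total += c * Fraction(t)
    return total


@dataclass(frozen=True)
class RatioSolution:
    """A strictly positive solution of the refocusing condition.

    ``lengths`` are normalized so the shortest pi-role pulse (or shortest
    pulse if no roles are given) equals 1; ``integer_form`` is the smallest
    primitive integer representative with coefficients <= the solver bound,
    or None.  ``unique`` is set when the positive solution set is a single
    ray (or single point under fixed lengths); ``family_dim`` counts the
    remaining free parameters beyond overall scaling.
    """

    lengths: tuple[Fraction, ...]
    signs: tuple[int, ...]
    residuals: tuple[Fraction, ...]
    normalized_total: Fraction
    unique: bool
    integer_form: tuple[int, ...] | None
    family_dim: int = 0
    roles: tuple[str, ...] | None = None


@dataclass(frozen=True)
class InfeasibleResult:
    """No strictly positive pulse lengths satisfy the constraints."""

    signs: tuple[int, ...]
    reason: str

    @property
    def feasible(self) -> bool:
        return False


def _rows(
    signs: Sequence[int], pathways: Iterable[CoherencePathway]
) -> list[tuple[int, ...]]:
    return [p.coefficients(signs) for p in pathways]


def _normalize(lengths, roles):
    lengths = tuple(Fraction(x) for x in lengths)
    if roles is not None:
        anchor = min(
            (l for l, r in zip(lengths, roles) if r == "pi"), default=min(lengths)
        )
    else:
        anchor = min(lengths)
    return tuple(l / anchor for l in lengths)


def _integer_form(lengths, max_coeff):
    """Smallest primitive integer multiple of a rational vector, or None."""
    dens = [Fraction(x).denominator for x in lengths]
    lcm = 1
    for d in dens:
        lcm = lcm * d // gcd(lcm, d)
    ints = [int(Fraction(x) * lcm) for x in lengths]
    g = 0
    for v in ints:
        g = gcd(g, v)
    if g:
        ints = [v // g for v in ints]
    if max(abs(v) for v in ints) > max_coeff:
        return None
    return tuple(ints)


def _ordering_violation(vec, roles) -> int:
    """1 if some pi-role pulse is not strictly longer than some pi/2 pulse."""
    if roles is None:
        return 0
    pis = [v for v, r in zip(vec, roles) if r == "pi"]
    halves = [v for v, r in zip(vec, roles) if r == "pi/2"]
    if not pis or not halves:
        return 0
    return 0 if min(pis) > max(halves) else 1


def _enumerate_family(rows, fixed, n, max_coeff):
    """All positive integer solutions (coeffs <= max_coeff) of the homogeneous
    system with optional fixed entries; primitive when fully free."""
    free = [i for i in range(n) if i not in fixed]
    if len(free) > 6:
        raise ValueError(
            "integer enumeration limited to 6 free pulse lengths; fix more"
        )
    sols = []
    for combo in itertools.product(range(1, max_coeff + 1), repeat=len(free)):
        vec = [Fraction(0)] * n
        for i, v in fixed.items():
            vec[i] = Fraction(v)
        for i, v in zip(free, combo):
            vec[i] = Fraction(v)
        if any(v <= 0 for v in vec):
            continue
        if all(
            sum(c * v for c, v in zip(row, vec)) == 0 for row in rows
        ):
            if not fixed:
                ints = [int(v) for v in vec]
                g = 0
                for v in ints:
                    g = gcd(g, v)
                if g > 1:
                    continue
            sols.append(tuple(vec))
    return sols


def solve_ratios(
    signs: Sequence[int],
    pathways: Sequence[CoherencePathway],
    *,
    fixed: dict[int, Fraction] | None = None,
    equal: Sequence[tuple[int, int]] | None = None,
    roles: Sequence[str] | None = None,
    max_coeff: int = 12,
) -> RatioSolution | InfeasibleResult:
    """Solve the refocusing condition for positive pulse-length ratios.

    Parameters
    ----------
    signs : sweep directions, one +-1 per pulse.
    pathways : coherence pathways (and pseudo-pathway constraints) whose
        residuals must all vanish.
    fixed : map pulse index -> prescribed relative length.
    equal : pairs of pulse indices constrained to equal length.
    roles : optional per-pulse flip tags ("pi/2"/"pi") used for
        normalization and for the family-selection preference.
    max_coeff : bound on integer coefficients searched/reported.

    Returns an exact :class:`RatioSolution`, or :class:`InfeasibleResult`
    when the nullspace meets the positive orthant only at the origin.
    """
    signs = tuple(int(s) for s in signs)
    if any(s not in (-1, 1) for s in signs):
        raise ValueError("sweep signs must be +1 or -1")
    n = len(signs)
    if not pathways:
        raise ValueError("at least one coherence pathway is required")
    fixed = {int(k): Fraction(v) for k, v in (fixed or {}).items()}
    roles_t = tuple(roles) if roles is not None else None

    rows = _rows(signs, pathways)
    if equal:
        for i, j in equal:
            row = [0] * n
            row[i], row[j] = 1, -1
            rows.append(tuple(row))

    # rational solve with sympy: A x = b after moving fixed lengths to rhs
    free = [i for i in range(n) if i not in fixed]
    A = sympy.Matrix(
        [[sympy.Rational(r[i]) for i in free] for r in rows]
    )
    b = sympy.Matrix(
        [
            [-sum(sympy.Rational(r[i]) * sympy.Rational(fixed[i]) for i in fixed)]
            for r in rows
        ]
    )
    try:
        sol, params = A.gauss_jordan_solve(b)
    except ValueError:
        return InfeasibleResult(signs, "constraints are mutually inconsistent")
    ndim = len(params)

    def assemble(free_vals):
        vec = [Fraction(0)] * n
        for i, v in fixed.items():
            vec[i] = v
        for i, v in zip(free, free_vals):
            vec[i] = Fraction(str(v)) if not isinstance(v, (int, Fraction)) else Fraction(v)
        return tuple(vec)

    homogeneous = not fixed

    if ndim == 0:
        vals = [Fraction(sympy.nsimplify(x)) for x in sol]
        vec = assemble(vals)
        if homogeneous or any(v <= 0 for v in vec):
            return InfeasibleResult(
                signs,
                "the unique solution has non-positive pulse lengths"
                if not homogeneous
                else "only the trivial all-zero solution exists",
            )
        return _finalize(vec, signs, pathways, roles_t, unique=True,
                         family_dim=0, max_coeff=max_coeff)

    if homogeneous and ndim == 1:
        basis = sol.subs(params[0], 1)
        vals = [Fraction(sympy.nsimplify(x)) for x in basis]
        if all(v < 0 for v in vals):
            vals = [-v for v in vals]
        vec = assemble(vals)
        if any(v <= 0 for v in vec):
            return InfeasibleResult(
                signs,
                "the solution ray leaves the positive orthant "
                "(negative pulse lengths would be required)",
            )
        return _finalize(vec, signs, pathways, roles_t, unique=True,
                         family_dim=0, max_coeff=max_coeff)

    # under-determined family (or affine with freedom): integer search
    candidates = _enumerate_family(rows, fixed, n, max_coeff)
    if not candidates:
        return InfeasibleResult(
            signs,
            f"no positive solution with integer coefficients <= {max_coeff}",
        )
    best = min(
        candidates,
        key=lambda v: (_ordering_violation(v, roles_t), sum(v), max(v), v),
    )
    family_dim = ndim - (1 if homogeneous else 0)
    return _finalize(best, signs, pathways, roles_t, unique=False,
                     family_dim=family_dim, max_coeff=max_coeff)


def _finalize(vec, signs, pathways, roles, unique, family_dim, max_coeff):
    residuals = tuple(eq_residual(vec, signs, p) for p in pathways)
    norm = _normalize(vec, roles)
    return RatioSolution(
        lengths=norm,
        signs=signs,
        residuals=residuals,
        normalized_total=sum(norm, Fraction(0)),
        unique=unique,
        integer_form=_integer_form(vec, max_coeff),
        family_dim=family_dim,
        roles=roles,
    )


def enumerate_patterns(
    n_pulses: int,
    pathways: Sequence[CoherencePathway],
    *,
    fixed: dict[int, Fraction] | None = None,
    equal: Sequence[tuple[int, int]] | None = None,
    roles: Sequence[str] | None = None,
    max_coeff: int = 12,
) -> list[tuple[tuple[int, ...], RatioSolution]]:
    """Solve every one of the 2**n sweep-direction patterns and rank the
    feasible ones by how short the sequence can be made.

    The ranking metric is the total length with the shortest pi-role pulse
    scaled to 1 (the shortest pi pulse sets the minimal absolute lengths);
    ties break on the longest single pulse, then on the sign pattern with up
    sweeps first.
    """
    if n_pulses > 10:
        raise ValueError("pattern enumeration is limited to 10 pulses (2^n)")
    out = []
    for signs in itertools.product((1, -1), repeat=n_pulses):
        res = solve_ratios(
            signs, pathways, fixed=fixed, equal=equal, roles=roles,
            max_coeff=max_coeff,
        )
        if isinstance(res, RatioSolution):
            out.append((signs, res))
    out.sort(
        key=lambda sr: (
            sr[1].normalized_total,
            max(sr[1].lengths),
            tuple(0 if s == 1 else 1 for s in sr[0]),
        )
    )
    return out


def verify_dual_refocusing(
    lengths: Sequence,
    signs: Sequence[int],
    pathways: Sequence[CoherencePathway],
    delays: Sequence | None = None,
) -> dict:
    """Check several pathways at once and predict their echo times.

    Returns the exact residual per pathway and, when center-to-center
    ``delays`` (one per pulse gap) are given, the echo time of each pathway
    after the last pulse center from the interval-order arithmetic
    ``t_k = -(sum_j o_j d_j)/o_det``, plus the pairwise separations.  A
    solution with all residuals zero refocuses the offsets of every pathway,
    but generally at different times.
    """
    if len(pathways) < 2:
        raise ValueError("dual refocusing needs at least two pathways")
    residuals = tuple(eq_residual(lengths, signs, p) for p in pathways)
    result = {"residuals": residuals}
    if delays is not None:
        delays = [Fraction(d) for d in delays]
        if len(delays) != len(lengths) - 1:
            raise ValueError("need one delay per pulse gap")
        times = []
        for p in pathways:
            o_after = [op for (_, op) in p.orders]
            det = o_after[-1]
            if det == 0:
                raise ValueError("detection-period coherence order is zero")
            t = -sum(o * d for o, d in zip(o_after[:-1], delays)) / det
            times.append(t)
        result["echo_times"] = tuple(times)
        result["separations"] = tuple(
            abs(a - b) for a, b in itertools.combinations(times, 2)
        )
    return result
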