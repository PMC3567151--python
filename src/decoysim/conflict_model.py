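"""Mathematical core of the sexual-conflict-with-decoy model.

Three diploid loci shape the mating rate of a male-female pair: a
male-expressed ligand, a female-expressed receptor, and a female-expressed
decoy that mimics the receptor.  Alleles are integers on ``[0, allele_max]``
and determine phenotypes additively; all distances are computed on
phenotypes normalized to ``[0, 1]``.

The pieces are:

* ``baseline_mating_rate`` -- the two-locus conflict: mating rate ``P_MF``
  decays with the male-female phenotypic distance ``D_MF``, so males (whose
  fitness rises with mating rate) are selected toward females, and females
  (whose fecundity peaks at an intermediate rate ``P_opt``) are selected
  away whenever ``P_MF > P_opt``.
* ``female_fecundity`` -- offspring number ``W_f`` falls off from ``B_max``
  as the realized mating rate deviates from ``P_opt``.
* ``decoy_modified_rate`` -- when the decoy phenotype lies strictly between
  the male and female phenotypes (activity indicator ``theta = 1``) it
  intercepts ligand and pulls the mating rate down to the female optimum
  (effectiveness ``Pe``), minus an interference term ``Pi`` that grows as
  the decoy approaches the female and as ``D_MF`` deviates from the optimal
  distance for decoy function ``D_opt`` (magnitude ``Pt``).

The decay / penalty curves are pluggable scale-exponent families
``exp(-(d/s)**x)`` with the defaults documented on :class:`ModelParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "ModelParams",
    "DecoyEffect",
    "phenotype",
    "baseline_mating_rate",
    "female_fecundity",
    "decoy_active",
    "decoy_modified_rate",
    "validate_params",
]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the conflict-with-decoy model.

    Attributes
    ----------
    P_opt : float
        Optimal female mating rate (probability per encounter, in (0, 1)).
    B_max : float
        Maximum offspring per female at the optimal mating rate.
    s_w, x_w : float
        Scale and exponent of the fecundity penalty
        ``W_f = B_max * exp(-(|P - P_opt| / s_w) ** x_w)``.
    s_p, x_p : float
        Scale and exponent of the baseline mating-rate decay
        ``P_MF = exp(-(D_MF / s_p) ** x_p)``.
    si, xi : float
        Scale and exponent of the positional part of decoy interference,
        ``c0 * P_opt * q`` with ``q = max(0, 1 - (rho/si)**xi)`` and
        ``rho = d_FD / D_MF`` the decoy's relative position between female
        (0) and male (1).  ``si`` lies in (0, 1]; with ``si = 1``
        interference vanishes exactly when the decoy reaches the male, so
        the mating rate of such a pair is exactly the female optimum.  The
        persistent gradient across the whole gap is what selects the decoy
        from the female toward the male.
    sd, xd : float
        Scale and exponent of the position-independent deviation penalty
        ``P_opt * min(1, (|D_MF - D_opt| / sd) ** xd)``, which punishes an
        active-decoy pair for sitting at the wrong distance regardless of
        where the decoy is.  The total interference magnitude is
        ``Pt = P_opt * min(1, (|D_MF - D_opt| / sd) ** xd + c0)``.
    c0 : float
        Positional interference magnitude as a fraction of ``P_opt``: the
        interference from a decoy sitting on the female at
        ``D_MF = D_opt`` (the decoy never functions perfectly).
    D_opt : float
        Optimal male-female phenotypic distance for decoy function, on the
        normalized scale.  A pair separated by exactly ``D_opt`` suffers
        only the baseline interference; deviation in either direction is
        penalized, which keeps the male and female loci apart while the
        decoy is active.
    allele_max : int
        Size of the allele space; valid allelic values are ``0..allele_max``.
    normalize : bool
        Divide phenotypes by ``allele_max`` before distance computations,
        so distances and ``D_opt`` live on ``[0, 1]``.

    Defaults place the decoy's operating distance ``D_opt = 0.1`` inside
    the band where the baseline rate exceeds the female optimum
    (``P_MF(0.1) = e^-1 > P_opt = 0.1``), so the decoy has a positive
    effectiveness ``Pe`` to work with.  The deviation penalty is V-shaped
    (``xd = 1``): a quadratic well has no restoring force at its center
    and lets the male drift onto the decoy, collapsing all three loci;
    the linear well holds the male (and female) at ``D_opt`` while the
    decoy is active.  It saturates (``Pt = P_opt``) at deviation ``sd =
    0.25``, well before the 0.5 deviation at which near-total suppression
    of mating is required to stop the decoy from chasing the male.  The
    fecundity penalty exponent ``x_w = 1.5`` sits between exponential and
    Gaussian: a Gaussian penalty makes offspring-number ratios explode far
    from the optimum (collapsing the effective population size whenever
    the pair is cornered at an allele-space boundary), while a pure
    exponential leaves the female too weakly selected to outrun the male.
    """

    P_opt: float = 0.1
    B_max: float = 10.0
    s_w: float = 0.15
    x_w: float = 1.5
    s_p: float = 0.1
    x_p: float = 2.0
    si: float = 1.0
    xi: float = 1.0
    sd: float = 0.25
    xd: float = 1.0
    c0: float = 0.2
    D_opt: float = 0.1
    allele_max: int = 50
    normalize: bool = True

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DecoyEffect:
    """Decomposition of the decoy's modification of a pair's mating rate.

    ``theta`` is the activity indicator (1 iff the decoy phenotype lies
    strictly between male and female).  When active, effectiveness
    ``Pe = max(P_MF - P_opt, 0)`` takes the rate down to the female
    optimum, and interference ``Pi`` (bounded by its magnitude ``Pt``)
    takes it further down: ``P_modified = clamp(min(P_MF, P_opt) - Pi)``.
    ``Pi`` is the sum of a positional part ``c0 * P_opt * q`` that declines
    as the decoy's relative position moves from the female to the male and
    a position-independent deviation penalty ``P_opt * min(1,
    (|D_MF - D_opt|/sd)**xd)``, capped at ``Pt``.  When inactive,
    ``P_modified = P_MF`` and the other fields are zero.
    """

    theta: int
    Pe: float
    Pi: float
    Pt: float
    P_modified: float


def _check_alleles(alleles: np.ndarray, allele_max: int) -> None:
    if np.any(alleles < 0) or np.any(alleles > allele_max):
        raise ValueError(
            f"allelic value outside allele space [0, {allele_max}]"
        )


def phenotype(allele_a, allele_b, params: ModelParams):
    """Additive phenotype of a diploid genotype: the mean of its two alleles.

    Normalized to [0, 1] (division by ``allele_max``) when
    ``params.normalize`` is set.  Accepts scalars or arrays.
    """
    a = np.asarray(allele_a, dtype=float)
    b = np.asarray(allele_b, dtype=float)
    _check_alleles(a, params.allele_max)
    _check_alleles(b, params.allele_max)
    z = (a + b) / 2.0
    if params.normalize:
        z = z / params.allele_max
    return z if z.ndim else float(z)


def baseline_mating_rate(D_MF, params: ModelParams):
    """Mating rate of a pair at phenotypic distance ``D_MF``, ignoring the decoy.

    ``P_MF = exp(-(D_MF / s_p) ** x_p)``: equal to 1 at zero distance and
    strictly decreasing, so males maximize mating rate by matching the
    female phenotype.
    """
    d = np.asarray(D_MF, dtype=float)
    if np.any(d < 0):
        raise ValueError("phenotypic distance must be non-negative")
    p = np.exp(-((d / params.s_p) ** params.x_p))
    return p if p.ndim else float(p)


def female_fecundity(P, params: ModelParams):
    """Expected offspring of a female with realized mating rate ``P``.

    ``W_f = B_max * exp(-(|P - P_opt| / s_w) ** x_w)``: maximal at the
    female optimum and symmetric in the deviation from it.
    """
    p = np.asarray(P, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("mating rate must lie in [0, 1]")
    w = params.B_max * np.exp(
        -((np.abs(p - params.P_opt) / params.s_w) ** params.x_w)
    )
    return w if w.ndim else float(w)


def decoy_active(z_m, z_f, z_d):
    """Decoy activity indicator theta.

    1 iff the decoy phenotype lies strictly between the male and female
    phenotypes (ties give 0: a decoy coincident with either party cannot be
    discriminated from it).  Accepts scalars or arrays.
    """
    z_m = np.asarray(z_m, dtype=float)
    z_f = np.asarray(z_f, dtype=float)
    z_d = np.asarray(z_d, dtype=float)
    lo = np.minimum(z_m, z_f)
    hi = np.maximum(z_m, z_f)
    theta = ((z_d > lo) & (z_d < hi)).astype(int)
    return theta if theta.ndim else int(theta)


def interference_magnitude(D_MF, params: ModelParams):
    """Magnitude ``Pt`` of female-decoy interference at male-female distance ``D_MF``.

    Grows from the baseline ``c0 * P_opt`` as ``D_MF`` deviates from the
    optimal distance for decoy function, saturating at ``P_opt``:
    ``Pt = P_opt * min(1, (|D_MF - D_opt| / sd) ** xd + c0)``.
    """
    d = np.asarray(D_MF, dtype=float)
    dev = np.abs(d - params.D_opt)
    pt = params.P_opt * np.minimum(1.0, (dev / params.sd) ** params.xd + params.c0)
    return pt if pt.ndim else float(pt)


def decoy_modified_rate(z_m, z_f, z_d, params: ModelParams) -> DecoyEffect:
    """Mating rate of a pair whose female carries an active or inactive decoy.

    Scalar phenotypes on the common (normalized) scale.  Returns the full
    :class:`DecoyEffect` decomposition; the population engine inlines the
    same algebra for speed.
    """
    _check_scalar_params(params)
    z_m, z_f, z_d = float(z_m), float(z_f), float(z_d)
    D_MF = abs(z_m - z_f)
    P_MF = baseline_mating_rate(D_MF, params)
    theta = decoy_active(z_m, z_f, z_d)
    if theta == 0:
        return DecoyEffect(theta=0, Pe=0.0, Pi=0.0, Pt=0.0, P_modified=P_MF)
    Pe = max(P_MF - params.P_opt, 0.0)
    Pt = interference_magnitude(D_MF, params)
    rho = abs(z_f - z_d) / D_MF  # relative position: 0 at female, 1 at male
    q = max(0.0, 1.0 - (rho / params.si) ** params.xi)
    dev = abs(D_MF - params.D_opt)
    Pi = params.P_opt * min(
        params.c0 * q + min(1.0, (dev / params.sd) ** params.xd),
        min(1.0, (dev / params.sd) ** params.xd + params.c0),
    )
    # The decoy never raises the rate above the unmodified P_MF.
    P_mod = min(P_MF, params.P_opt) - Pi
    P_mod = min(max(P_mod, 0.0), 1.0)
    return DecoyEffect(theta=1, Pe=Pe, Pi=Pi, Pt=Pt, P_modified=P_mod)


def _check_scalar_params(p: ModelParams) -> None:
    """Range checks only (no feasibility grid); raises ConfigurationError."""
    if not (0.0 < p.P_opt < 1.0):
        raise ConfigurationError("P_opt must lie in (0, 1)")
    if p.B_max <= 0:
        raise ConfigurationError("B_max must be positive")
    for name in ("s_w", "x_w", "s_p", "x_p", "si", "xi", "sd", "xd"):
        if getattr(p, name) <= 0:
            raise ConfigurationError(f"{name} must be positive")
    if p.c0 < 0:
        raise ConfigurationError("c0 must be non-negative")
    if p.allele_max <= 0:
        raise ConfigurationError("allele_max must be positive")
    if p.normalize and not (0.0 <= p.D_opt <= 1.0):
        raise ConfigurationError("D_opt must lie in [0, 1] on the normalized scale")
    if p.si > 1.0:
        raise ConfigurationError(
            "si must lie in (0, 1]: interference must vanish by the time "
            "the decoy reaches the male"
        )


def validate_params(params: ModelParams) -> ModelParams:
    """Check scalar invariants and model-level feasibility; return ``params``.

    Beyond range checks, two conditions from the model's logic are
    enforced:

    * **Pi < Pe feasibility** -- the decoy must leave the female better off
      than the unmodified rate would.  At the decoy's operating distance
      ``D_MF = D_opt`` the effectiveness ``Pe = P_MF(D_opt) - P_opt`` must
      be positive and exceed the interference ``Pi`` for every decoy
      position in the interval, and the mean fecundity gain
      ``W_f(P_modified) - W_f(P_MF)`` over the active region where
      ``P_MF > P_opt`` must be positive.
    * **Pt ~ P_opt at deviation 0.5** -- the penalty for deviation from
      ``D_opt`` must be large enough (``Pt(|D_MF - D_opt| = 0.5) >= 0.9 *
      P_opt``) that a decoy cannot profitably chase the male far from the
      female.
    """
    p = params
    _check_scalar_params(p)

    # Pi < Pe feasibility at the operating distance D_MF = D_opt.
    P_at_opt = float(np.exp(-((p.D_opt / p.s_p) ** p.x_p)))
    Pe_at_opt = P_at_opt - p.P_opt
    Pt_at_opt = p.P_opt * min(1.0, p.c0)
    rho = np.linspace(0.0, 1.0, 101)
    Pi_at_opt = Pt_at_opt * np.maximum(0.0, 1.0 - (rho / p.si) ** p.xi)
    if Pe_at_opt <= 0 or float(Pi_at_opt.max()) >= Pe_at_opt:
        raise ConfigurationError(
            "Pi<Pe violated: decoy interference is not smaller than decoy "
            "effectiveness at the operating distance D_opt "
            f"(max Pi={float(Pi_at_opt.max()):.4g}, Pe={Pe_at_opt:.4g})"
        )
    # Mean fecundity gain over the active region where P_MF > P_opt.
    d_hi = p.s_p * (-np.log(p.P_opt)) ** (1.0 / p.x_p)  # P_MF(d_hi) = P_opt
    gains = []
    for D in np.linspace(1e-6, d_hi * (1 - 1e-6), 41):
        P_MF = float(np.exp(-((D / p.s_p) ** p.x_p)))
        dev = abs(D - p.D_opt)
        for frac in np.linspace(0.0, 1.0, 21):
            # frac = 0 puts the decoy at the female, frac = 1 at the male
            q = max(0.0, 1.0 - (frac / p.si) ** p.xi)
            Pi = p.P_opt * min(
                p.c0 * q + min(1.0, (dev / p.sd) ** p.xd),
                min(1.0, (dev / p.sd) ** p.xd + p.c0),
            )
            P_mod = min(max(min(P_MF, p.P_opt) - Pi, 0.0), 1.0)
            w_mod = p.B_max * np.exp(-((abs(P_mod - p.P_opt) / p.s_w) ** p.x_w))
            w_raw = p.B_max * np.exp(-((abs(P_MF - p.P_opt) / p.s_w) ** p.x_w))
            gains.append(w_mod - w_raw)
    if float(np.mean(gains)) <= 0:
        raise ConfigurationError(
            "Pi<Pe violated: mean female fecundity gain from the decoy is "
            "not positive over the active region"
        )

    pt_half = p.P_opt * min(1.0, (0.5 / p.sd) ** p.xd + p.c0)
    if pt_half < 0.9 * p.P_opt:
        raise ConfigurationError(
            "Pt~P_opt at 0.5 violated: interference magnitude at "
            f"|D_MF - D_opt| = 0.5 is {pt_half:.4g} < 0.9 * P_opt"
        )
    return params
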