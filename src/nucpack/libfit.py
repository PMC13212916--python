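"""Rotamer-library derivation from glycosidic-angle samples.

Preferred chi angles of nucleosides are extracted from chi-angle
populations by univariate Gaussian mixture modelling.  Two library
flavours are supported:

* ``pucker`` — the sugar-pucker-dependent library: chi samples are
  split per nucleoside into 2'-endo-like and 3'-endo-like classes and a
  mixture is fitted per (nucleoside, class) group.  The number of
  components is chosen as the first local minimum of the Bayesian
  information criterion over a 1..20 scan, followed by curation:
  models with two adjacent peaks closer than 10 deg are rejected (the
  scan falls back to fewer components), and components with weight
  below 1% or standard deviation above 50 deg are dropped with the
  remaining weights renormalised.
* ``basic`` — a pucker-independent library with one Gaussian fitted
  per user-specified chi window; rotamer probabilities are the areas
  under the fitted curves normalised to 1.

Angles live on [0, 360); the chi distributions of nucleotides have no
mass near the 0/360 seam, so plain (non-circular) Gaussians apply.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .structure import NUCLEOSIDES

__all__ = [
    "GmmComponent",
    "GmmModel",
    "ModelRejectedError",
    "RotamerEntry",
    "RotamerLibrary",
    "fit_gmm",
    "scan_components",
    "curate",
    "build_pucker_library",
    "build_basic",
    "read_library",
    "write_library",
]

PUCKER_CLASSES = ("ENDO2", "ENDO3")
GROUP_ANY = "ANY"

#: Curation thresholds: minimal peak separation, minimal weight, maximal sd.
MIN_PEAK_SEPARATION = 10.0
MIN_WEIGHT = 0.01
MAX_SD = 50.0


class ModelRejectedError(ValueError):
    """A mixture model failed curation (adjacent peaks closer than 10 deg)."""


@dataclass(frozen=True)
class GmmComponent:
    mean: float
    sd: float
    weight: float


@dataclass(frozen=True)
class GmmModel:
    """A fitted univariate mixture with its BIC bookkeeping."""

    components: Tuple[GmmComponent, ...]
    loglik: float
    k_params: int
    n: int

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k_params * math.log(self.n)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])


def _sorted_components(means, sds, weights) -> Tuple[GmmComponent, ...]:
    order = np.argsort(means)
    return tuple(
        GmmComponent(float(means[i]), float(sds[i]), float(weights[i])) for i in order
    )


def fit_gmm(
    samples: Sequence[float],
    n_components: int,
    seed: int = 0,
    n_init: int = 5,
    tol: float = 1e-4,
) -> GmmModel:
    """Fit a univariate Gaussian mixture by EM.

    Runs ``n_init`` k-means++-seeded restarts and keeps the best
    likelihood; components are returned sorted by mean.  The free
    parameter count for the BIC is ``3 k - 1`` (means, variances and
    weights minus the simplex constraint).
    """
    x = np.asarray(samples, dtype=float).reshape(-1, 1)
    if len(x) < 10 * n_components:
        raise ValueError(
            f"need at least {10 * n_components} samples for {n_components} "
            f"components, got {len(x)}"
        )
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        tol=tol,
        n_init=n_init,
        init_params="k-means++",
        max_iter=500,
        random_state=seed,
    )
    gm.fit(x)
    if not gm.converged_:
        warnings.warn(
            f"EM did not converge for k={n_components}; keeping best-so-far",
            RuntimeWarning,
        )
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    loglik = float(gm.score(x) * len(x))
    return GmmModel(_sorted_components(means, sds, weights), loglik, 3 * n_components - 1, len(x))


def scan_components(
    samples: Sequence[float],
    k_min: int = 1,
    k_max: int = 20,
    seed: int = 0,
) -> Tuple[List[GmmModel], int]:
    """Fit mixtures for k = k_min..k_max and pick the first local BIC minimum.

    Returns the fitted models and the index (into the returned list) of
    the selected model: the first k with ``BIC[k] < BIC[k-1]`` and
    ``BIC[k] <= BIC[k+1]``.  Fitting stops as soon as that index is
    confirmed — models at larger k cannot change the first local
    minimum, so the scan is truncated there.  If the BIC decreases
    monotonically to ``k_max``, the last model is selected with a
    warning.
    """
    n = len(samples)
    k_hi = min(k_max, max(k_min, n // 10))
    models: List[GmmModel] = []
    for k in range(k_min, k_hi + 1):
        models.append(fit_gmm(samples, k, seed=seed))
        if len(models) < 2:
            continue
        bics = [m.bic for m in models]
        i = len(models) - 2  # candidate index, now that its successor exists
        left_ok = i == 0 or bics[i] < bics[i - 1]
        if left_ok and bics[i] <= bics[i + 1]:
            return models, i
    warnings.warn("BIC decreased monotonically; selecting k_max", RuntimeWarning)
    return models, len(models) - 1


def curate(model: GmmModel) -> GmmModel:
    """Apply the library curation rules to a fitted mixture.

    Raises :class:`ModelRejectedError` when two adjacent component
    means are separated by less than 10 deg (the caller falls back to a
    model with fewer components).  Otherwise components with weight
    below 1% or standard deviation above 50 deg are removed and the
    remaining weights renormalised to sum to 1.
    """
    comps = model.components  # already sorted by mean
    for a, b in zip(comps, comps[1:]):
        if b.mean - a.mean < MIN_PEAK_SEPARATION:
            raise ModelRejectedError(
                f"adjacent peaks at {a.mean:.1f} and {b.mean:.1f} deg closer "
                f"than {MIN_PEAK_SEPARATION} deg"
            )
    kept = [c for c in comps if c.weight >= MIN_WEIGHT and c.sd <= MAX_SD]
    if not kept:
        raise ValueError("curation removed all components")
    total = sum(c.weight for c in kept)
    new = tuple(GmmComponent(c.mean, c.sd, c.weight / total) for c in kept)
    return GmmModel(new, model.loglik, model.k_params, model.n)


@dataclass(frozen=True)
class RotamerEntry:
    """One rotamer: integer chi mean, spread, and occurrence probability."""

    nucleoside: str
    pucker_class: str  # "ENDO2", "ENDO3" or "ANY"
    chi: int
    sd: float
    probability: float


@dataclass
class RotamerLibrary:
    """Nucleoside- (and optionally pucker-class-) keyed rotamer entries."""

    entries: List[RotamerEntry] = field(default_factory=list)
    flavor: str = "pucker"  # "pucker" (P-dependent) or "basic"
    provenance: str = ""

    def group(self, nucleoside: str, pucker_class: Optional[str] = None) -> List[RotamerEntry]:
        """Entries for a nucleoside; the basic flavour ignores the class."""
        key = GROUP_ANY if self.flavor == "basic" else pucker_class
        if key is None:
            raise ValueError("pucker class required for the pucker-dependent library")
        out = [
            e for e in self.entries
            if e.nucleoside == nucleoside and e.pucker_class == key
        ]
        return sorted(out, key=lambda e: e.chi)

    def groups(self) -> Dict[Tuple[str, str], List[RotamerEntry]]:
        out: Dict[Tuple[str, str], List[RotamerEntry]] = {}
        for e in self.entries:
            out.setdefault((e.nucleoside, e.pucker_class), []).append(e)
        return out

    def validate(self) -> None:
        for (nuc, cls), entries in self.groups().items():
            total = sum(e.probability for e in entries)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"group ({nuc}, {cls}) probabilities sum to {total}")
            if not 1 <= len(entries) <= 8:
                raise ValueError(f"group ({nuc}, {cls}) has {len(entries)} entries")
            if self.flavor == "basic" and cls != GROUP_ANY:
                raise ValueError("basic library must use class ANY")
            if self.flavor == "pucker" and cls not in PUCKER_CLASSES:
                raise ValueError("pucker-dependent library must use ENDO2/ENDO3")


def _entries_from_model(model: GmmModel, nucleoside: str, pucker_class: str) -> List[RotamerEntry]:
    # chi means are rounded to integers; probabilities stay as fitted
    return [
        RotamerEntry(nucleoside, pucker_class, int(round(c.mean)), c.sd, c.weight)
        for c in model.components
    ]


def _fit_group(samples: Sequence[float], seed: int) -> GmmModel:
    """Scan, select by first BIC minimum, curate with fewer-component fallback."""
    models, sel = scan_components(samples, seed=seed)
    last_err: Optional[Exception] = None
    for i in range(sel, -1, -1):
        try:
            return curate(models[i])
        except ModelRejectedError as err:
            last_err = err
    raise ValueError(f"no component count passed curation: {last_err}")


def build_pucker_library(
    samples_by_group: Mapping[Tuple[str, str], Sequence[float]],
    seed: int = 0,
) -> RotamerLibrary:
    """Build the sugar-pucker-dependent library from grouped chi samples.

    ``samples_by_group`` maps ``(nucleoside, pucker_class)`` to chi
    sample lists in degrees on [0, 360).
    """
    lib = RotamerLibrary(flavor="pucker", provenance="fitted from chi samples")
    for (nuc, cls), samples in sorted(samples_by_group.items()):
        if nuc not in NUCLEOSIDES or cls not in PUCKER_CLASSES:
            raise ValueError(f"unknown group ({nuc}, {cls})")
        try:
            model = _fit_group(samples, seed=seed)
        except Exception as err:
            raise ValueError(f"group ({nuc}, {cls}): {err}") from err
        lib.entries.extend(_entries_from_model(model, nuc, cls))
    lib.validate()
    return lib


def build_basic(
    samples_by_nucleoside: Mapping[str, Sequence[float]],
    peak_windows: Mapping[str, Sequence[Tuple[float, float]]],
) -> RotamerLibrary:
    """Build the pucker-independent library from per-peak Gaussian fits.

    One Gaussian is fitted (by moments) to the samples inside each
    user-specified chi window; the probability of a rotamer is the area
    under its fitted curve divided by the sum of all fitted areas.  The
    in-window sample count is corrected for the mass the fitted curve
    carries outside the window, so the area reflects the full curve.
    """
    lib = RotamerLibrary(flavor="basic", provenance="per-window Gaussian fits")
    for nuc, samples in sorted(samples_by_nucleoside.items()):
        x = np.asarray(samples, dtype=float)
        windows = list(peak_windows[nuc])
        for lo, hi in windows:
            if not (0.0 <= lo < hi <= 360.0):
                raise ValueError(f"invalid window [{lo}, {hi}]")
        for (lo, hi), (lo2, hi2) in zip(sorted(windows), sorted(windows)[1:]):
            if hi > lo2:
                raise ValueError("windows must not overlap")
        fits = []
        for lo, hi in windows:
            inside = x[(x >= lo) & (x < hi)]
            if len(inside) < 2:
                warnings.warn(f"window [{lo}, {hi}] for {nuc} is empty; skipped")
                continue
            mu = float(np.mean(inside))
            sd = float(np.std(inside, ddof=1))
            coverage = norm.cdf(hi, mu, sd) - norm.cdf(lo, mu, sd)
            area = len(inside) / max(coverage, 1e-12)
            fits.append((mu, sd, area))
        if not fits:
            raise ValueError(f"no usable windows for {nuc}")
        total = sum(a for _, _, a in fits)
        for mu, sd, area in fits:
            lib.entries.append(
                RotamerEntry(nuc, GROUP_ANY, int(round(mu)), sd, area / total)
            )
    # renormalise exactly after rounding of areas
    for (nuc, cls), entries in lib.groups().items():
        s = sum(e.probability for e in entries)
        if abs(s - 1.0) > 1e-12:
            for e in list(entries):
                lib.entries[lib.entries.index(e)] = RotamerEntry(
                    e.nucleoside, e.pucker_class, e.chi, e.sd, e.probability / s
                )
    lib.validate()
    return lib


_HEADER = "nucleoside\tclass\tchi\tsd\tprobability"


def write_library(lib: RotamerLibrary, path: str) -> None:
    """Serialise a library as TSV (bit-exact round-trip with read_library)."""
    lines = [_HEADER]
    for e in lib.entries:
        lines.append(
            f"{e.nucleoside}\t{e.pucker_class}\t{e.chi}\t{e.sd!r}\t{e.probability!r}"
        )
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_library(path: str, flavor: Optional[str] = None) -> RotamerLibrary:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or lines[0] != _HEADER:
        raise ValueError(f"{path}: not a rotamer-library TSV")
    entries = []
    for ln in lines[1:]:
        nuc, cls, chi, sd, prob = ln.split("\t")
        entries.append(RotamerEntry(nuc, cls, int(chi), float(sd), float(prob)))
    if flavor is None:
        flavor = "basic" if any(e.pucker_class == GROUP_ANY for e in entries) else "pucker"
    lib = RotamerLibrary(entries=entries, flavor=flavor, provenance=f"read from {path}")
    lib.validate()
    return lib
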