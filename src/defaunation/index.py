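"""The weighted defaunation index and its inputs.

The index compares a focal assemblage f against a reference assemblage r
(typically the historically expected community from range maps, or a
less-disturbed site):

    D(r, f) = sum_k w_k (N_kr - N_kf) / sum_k w_k (N_kr + N_kf)

with N in {0, 1} for presence/absence (or in (0, 1) when occupancy
probabilities are substituted; see :mod:`defaunation.montecarlo`). D lies
in [-1, 1]; positive values mean the focal assemblage is more defaunated
than the reference, negative values less.

Species importance weights w_k:

``equal``
    1 for every unit.
``conservation``
    IUCN threat rank: LC=1, NT=2, VU=3, EN=4, CR=5; Data Deficient units
    get the midpoint 2.5.
``size``
    body mass (g) raised to the 3/4 power, the metabolic scaling exponent,
    so weight tracks approximate ecosystem-function contribution.
``rank``
    ascending body-mass rank (1 = lightest, ties averaged) — a robustness
    variant that keeps the ordering of ``size`` but discards its scale.

A unit is *functionally extinct* at a site if it was recorded at fewer
than 2.5% of the site's camera stations: too rare to be an ecologically
functional population, even if not strictly absent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError

WEIGHT_SCHEMES = ("equal", "conservation", "size", "rank")

CONSERVATION_WEIGHTS = {
    "LC": 1.0, "NT": 2.0, "VU": 3.0, "EN": 4.0, "CR": 5.0,
    # Data Deficient: midpoint of the 1..5 scale rather than a guess at
    # either extreme.
    "DD": 2.5,
}

DEFAULT_EXTINCTION_THRESHOLD = 0.025


def species_weights(traits: pd.DataFrame, scheme: str = "equal") -> pd.Series:
    """Per-unit importance weights under one of the four schemes.

    Parameters
    ----------
    traits : DataFrame
        Must carry ``unit_id`` plus ``iucn`` (conservation scheme) or
        ``body_mass_g`` (size and rank schemes).

    Returns
    -------
    Series indexed by unit_id.
    """
    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"unknown weight scheme {scheme!r}; "
                         f"expected one of {WEIGHT_SCHEMES}")
    idx = pd.Index(traits["unit_id"], name="unit_id")
    if scheme == "equal":
        return pd.Series(1.0, index=idx)
    if scheme == "conservation":
        iucn = traits["iucn"]
        missing = list(idx[iucn.isna() | ~iucn.isin(CONSERVATION_WEIGHTS)])
        if missing:
            raise ConfigurationError(
                f"units lacking a valid IUCN category for the conservation "
                f"scheme: {missing}")
        return pd.Series(iucn.map(CONSERVATION_WEIGHTS).to_numpy(), index=idx)
    mass = pd.to_numeric(traits["body_mass_g"], errors="coerce")
    bad = list(idx[mass.isna() | (mass <= 0)])
    if bad:
        raise ConfigurationError(
            f"units lacking a positive body mass for the {scheme} scheme: {bad}")
    if scheme == "size":
        return pd.Series(np.power(mass.to_numpy(), 0.75), index=idx)
    # rank: lightest unit gets rank 1, ties share the average rank
    return pd.Series(mass.rank(method="average").to_numpy(), index=idx)


def functional_extinction(presence: pd.DataFrame,
                          threshold: float = DEFAULT_EXTINCTION_THRESHOLD,
                          reference_units=None) -> pd.Series:
    """Classify units as functionally present (1) or extinct (0) at a site.

    A unit is functionally extinct if recorded at strictly fewer than
    ``threshold`` (default 2.5%) of the site's stations. The inequality is
    strict: a unit at exactly the threshold fraction survives. Never-recorded
    units — including reference units with no detections at all — are
    functionally extinct.

    Parameters
    ----------
    presence : DataFrame
        Units x stations binary matrix for one site
        (:func:`defaunation.histories.station_presence`).
    threshold : float
        Station fraction in the open interval (0, 1).
    reference_units : sequence, optional
        Full unit list of the reference assemblage; units absent from
        ``presence`` rows are scored 0.

    Returns
    -------
    Series of {0, 1} indexed by unit.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    n_stations = presence.shape[1]
    if n_stations == 0:
        raise ValueError("presence matrix has no stations")
    frac = presence.to_numpy().astype(float).sum(axis=1) / n_stations
    focal = pd.Series((frac >= threshold).astype(int), index=presence.index)
    if reference_units is not None:
        focal = focal.reindex(pd.Index(reference_units), fill_value=0)
    return focal


def _aligned(reference, focal, weights):
    ref = pd.Series(reference) if not isinstance(reference, pd.Series) else reference
    foc = pd.Series(focal) if not isinstance(focal, pd.Series) else focal
    if list(ref.index) != list(foc.index):
        foc = foc.reindex(ref.index)
        if foc.isna().any():
            missing = list(foc.index[foc.isna()])
            raise ConfigurationError(
                f"focal assemblage missing units present in reference: {missing}")
    if weights is None:
        w = pd.Series(1.0, index=ref.index)
    elif isinstance(weights, pd.Series):
        w = weights.reindex(ref.index)
        if w.isna().any():
            missing = list(w.index[w.isna()])
            raise ConfigurationError(f"weights missing for units: {missing}")
    else:
        w = pd.Series(np.asarray(weights, dtype=float), index=ref.index)
    return ref.to_numpy(dtype=float), foc.to_numpy(dtype=float), w.to_numpy(dtype=float)


def defaunation_index(reference, focal, weights=None) -> float:
    """Evaluate D(r, f) for aligned assemblages.

    Parameters
    ----------
    reference, focal : Series or array
        Presence/absence in {0, 1} (or occupancy probabilities in [0, 1]);
        Series inputs are aligned on the reference index.
    weights : Series, array or None
        Nonnegative unit weights; None means equal weights.

    Raises
    ------
    ValueError
        If the denominator vanishes (both assemblages empty under the
        weights) or weights are negative/non-finite.
    """
    ref, foc, w = _aligned(reference, focal, weights)
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and nonnegative")
    if np.any((ref < 0) | (ref > 1)) or np.any((foc < 0) | (foc > 1)):
        raise ValueError("assemblage values must lie in [0, 1]")
    denom = float(np.sum(w * (ref + foc)))
    if denom <= 0:
        raise ValueError(
            "defaunation index undefined: no unit present in either "
            "assemblage under these weights")
    return float(np.sum(w * (ref - foc)) / denom)


def site_defaunation(presence_by_site: dict[str, pd.DataFrame],
                     reference_assemblage: pd.Series,
                     traits: pd.DataFrame,
                     schemes=("equal", "conservation", "size"),
                     threshold: float = DEFAULT_EXTINCTION_THRESHOLD) -> pd.DataFrame:
    """Historical defaunation of each site under each weight scheme.

    For every site: apply the functional-extinction rule to its presence
    matrix, then evaluate D against the reference assemblage under each
    scheme. Returns a site x scheme DataFrame of D values.
    """
    units = reference_assemblage.index
    rows = {}
    for site, presence in presence_by_site.items():
        focal = functional_extinction(presence, threshold=threshold,
                                      reference_units=units)
        rows[site] = {
            scheme: defaunation_index(
                reference_assemblage, focal,
                species_weights(traits, scheme).reindex(units))
            for scheme in schemes
        }
    return pd.DataFrame(rows).T[list(schemes)]
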