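"""Distance-modified exposure construction for spatially misaligned monitoring data.

Chemical concentrations are measured at monitoring sites that do not coincide
with participant residences. Exposure at a residence is summarised as an
inverse-distance functional of all site measurements of a chemical,

    x_i = sum_j c_j / d_ij^p,        p in {1, 2},

with d_ij the great-circle distance (spherical law of cosines) from residence
i to site j. Each participant carries up to three address classes — first
(birth), longest (longest-held) and last (current) residence — proxies for
early, cumulative and recent exposure windows.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "EARTH_RADIUS_KM",
    "ADDRESS_CLASSES",
    "MEDIUM_SUFFIX",
    "great_circle_distance",
    "distance_weight",
    "build_exposure_matrix",
    "distance_histogram",
    "InverseDistanceExposure",
]

#: conventional mean Earth radius, km
EARTH_RADIUS_KM = 6371.0

#: exposure-window proxies, in narrative order
ADDRESS_CLASSES = ("first", "longest", "last")

#: medium -> column-label suffix ("mercuryS", "arsenicW", bare name for strip metals)
MEDIUM_SUFFIX = {"soil": "S", "groundwater": "W", "strip": ""}

#: distances below this are clamped so a residence on a site stays finite
MIN_DISTANCE_KM = 0.1


def _validate_lonlat(lon, lat) -> tuple[np.ndarray, np.ndarray]:
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
        raise ValueError("coordinates out of range: need lat in [-90, 90], lon in [-180, 180]")
    return lon, lat


def great_circle_distance(a, b) -> np.ndarray:
    """Great-circle distance in km by the spherical law of cosines.

    Parameters
    ----------
    a, b : (lon, lat) pairs in decimal degrees (WGS84); arrays broadcast.

    Returns
    -------
    Distance(s) in km on a sphere of radius 6371.0 km.
    """
    lon1, lat1 = _validate_lonlat(a[0], a[1])
    lon2, lat2 = _validate_lonlat(b[0], b[1])
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(lon2) - np.radians(lon1)
    cosang = np.sin(phi1) * np.sin(phi2) + np.cos(phi1) * np.cos(phi2) * np.cos(dlam)
    # round-off for near-identical points can push |cosang| slightly past 1
    d = EARTH_RADIUS_KM * np.arccos(np.clip(cosang, -1.0, 1.0))
    return d if d.ndim else float(d)


def distance_weight(
    concentrations: Sequence[float],
    distances: Sequence[float],
    p: int = 1,
    normalize: bool = False,
    clamp_km: float = MIN_DISTANCE_KM,
) -> float:
    """Collapse one chemical's site measurements into a scalar exposure.

    ``sum_j c_j / d_j^p`` over the sites measuring the chemical; with
    ``normalize=True`` the inverse-distance weights are renormalised to sum
    to one (a classical IDW mean) instead.

    Raises
    ------
    ValueError
        If the site set is empty (chemical unmeasured in the medium) or
        lengths differ.
    """
    c = np.asarray(concentrations, dtype=float)
    d = np.asarray(distances, dtype=float)
    if c.size == 0:
        raise ValueError("chemical unmeasured in medium: empty site set")
    if c.shape != d.shape:
        raise ValueError(f"length mismatch: {c.shape} concentrations vs {d.shape} distances")
    if p not in (1, 2):
        raise ValueError(f"weighting power must be 1 or 2, got {p!r}")
    w = 1.0 / np.maximum(d, clamp_km) ** p
    if normalize:
        return float(np.sum(w * c) / np.sum(w))
    return float(np.sum(w * c))


def _column_label(chemical: str, medium: str) -> str:
    try:
        return f"{chemical}{MEDIUM_SUFFIX[medium]}"
    except KeyError:
        raise ValueError(f"unknown medium {medium!r}; expected one of {sorted(MEDIUM_SUFFIX)}")


class InverseDistanceExposure(BaseEstimator, TransformerMixin):
    """Transformer from addresses to a distance-weighted exposure matrix.

    ``fit`` ingests the site-measurement table; ``transform`` maps an address
    table (participant_id, address_class, lon, lat) to a participants x
    chemical-medium DataFrame of inverse-distance exposures.

    Parameters
    ----------
    address_class : which residence to use ("first", "longest", "last").
    media : media to include; columns are one per chemical-medium pair.
    p : inverse-distance power, 1 (linear) or 2 (quadratic).
    normalize : if True use the renormalised IDW mean instead of the raw sum.
    clamp_km : lower clamp on distances, km.
    """

    def __init__(
        self,
        address_class: str = "first",
        media: Iterable[str] = ("soil", "groundwater"),
        p: int = 1,
        normalize: bool = False,
        clamp_km: float = MIN_DISTANCE_KM,
    ):
        self.address_class = address_class
        self.media = media
        self.p = p
        self.normalize = normalize
        self.clamp_km = clamp_km

    def fit(self, X: pd.DataFrame, y=None):
        """Store the site-measurement table X (site_id, lon, lat, medium, chemical, concentration)."""
        required = {"site_id", "lon", "lat", "medium", "chemical", "concentration"}
        missing = required - set(X.columns)
        if missing:
            raise ValueError(f"site table missing columns: {sorted(missing)}")
        if (X["concentration"] < 0).any():
            raise ValueError("negative concentration in site table")
        media = tuple(self.media)
        sub = X[X["medium"].isin(media)]
        groups = []
        for (medium, chemical), g in sub.groupby(["medium", "chemical"], sort=True):
            groups.append((_column_label(chemical, medium), g))
        # column order: media in requested order, chemicals alphabetical within
        order = {m: i for i, m in enumerate(media)}
        groups.sort(key=lambda t: (order[t[1]["medium"].iloc[0]], t[0]))
        self.measurements_ = sub.reset_index(drop=True)
        self.columns_ = [label for label, _ in groups]
        self._groups_ = groups
        return self

    def transform(self, addresses: pd.DataFrame) -> pd.DataFrame:
        """Compute the exposure matrix for the fitted sites at the given addresses."""
        if not hasattr(self, "_groups_"):
            raise RuntimeError("InverseDistanceExposure is not fitted")
        addr = addresses[addresses["address_class"] == self.address_class]
        requested = addresses["participant_id"].unique()
        dropped = set(requested) - set(addr["participant_id"])
        if dropped:
            logger.warning(
                "%d participant(s) missing a %r address; rows omitted: %s",
                len(dropped), self.address_class, sorted(dropped),
            )
        if addr.empty:
            raise ValueError(f"no participant has a {self.address_class!r} address")
        lon, lat = _validate_lonlat(addr["lon"].to_numpy(), addr["lat"].to_numpy())
        rows = {}
        for label, g in self._groups_:
            d = great_circle_distance(
                (lon[:, None], lat[:, None]),
                (g["lon"].to_numpy()[None, :], g["lat"].to_numpy()[None, :]),
            )
            w = 1.0 / np.maximum(d, self.clamp_km) ** self.p
            c = g["concentration"].to_numpy()
            vals = w @ c
            if self.normalize:
                vals = vals / w.sum(axis=1)
            rows[label] = vals
        out = pd.DataFrame(rows, index=pd.Index(addr["participant_id"], name="participant_id"))
        out = out[self.columns_]
        out.attrs["address_class"] = self.address_class
        out.attrs["power"] = self.p
        out.attrs["media"] = tuple(self.media)
        return out


def build_exposure_matrix(
    addresses: pd.DataFrame,
    measurements: pd.DataFrame,
    address_class: str = "first",
    media: Iterable[str] = ("soil", "groundwater"),
    p: int = 1,
    normalize: bool = False,
) -> pd.DataFrame:
    """One-shot wrapper over :class:`InverseDistanceExposure`."""
    tr = InverseDistanceExposure(
        address_class=address_class, media=media, p=p, normalize=normalize
    )
    return tr.fit(measurements).transform(addresses)


def distance_histogram(
    addresses: pd.DataFrame,
    sites: pd.DataFrame,
    bin_km: float = 1.0,
    max_km: float | None = None,
) -> pd.DataFrame:
    """Binned counts of all address-site great-circle distances per address class.

    Mirrors the diagnostic histograms used to check that residences sit
    mostly within ~15 km of monitoring sites. The last bin is open-ended so
    counts always total n_addresses x n_sites per class.
    """
    if addresses.empty or sites.empty:
        raise ValueError("addresses and sites must be nonempty")
    slon, slat = _validate_lonlat(sites["lon"].to_numpy(), sites["lat"].to_numpy())
    records = []
    for cls, g in addresses.groupby("address_class"):
        lon, lat = _validate_lonlat(g["lon"].to_numpy(), g["lat"].to_numpy())
        d = great_circle_distance(
            (lon[:, None], lat[:, None]), (slon[None, :], slat[None, :])
        ).ravel()
        top = max_km if max_km is not None else float(np.ceil(d.max() / bin_km) * bin_km)
        top = max(top, bin_km)
        edges = np.arange(0.0, top + bin_km, bin_km)
        counts, _ = np.histogram(np.minimum(d, top - 1e-12), bins=edges)
        for lo, hi, n in zip(edges[:-1], edges[1:], counts):
            records.append(
                {"address_class": cls, "bin_lo_km": lo, "bin_hi_km": hi, "count": int(n)}
            )
    return pd.DataFrame.from_records(records)
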