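"""Design-matrix construction for the censored Weibull regression.

Terms supported:

* continuous covariates in their native units (so each coefficient is a
  per-unit effect on log mean concentration);
* categorical covariates under sum-to-zero contrasts, so remaining terms
  read as overall-average relationships and the K-th level coefficient is
  recoverable as minus the sum of the other K−1;
* (categorical × continuous) interactions as elementwise products of every
  contrast column with the continuous covariate — interaction coefficients
  are category-specific deviations from the average slope;
* Legendre polynomials of longitude/latitude rescaled to [−1, 1] over a
  stored bounding box (degree ≤ 2, with cross products P1·P1, P1·P2, P2·P1);
* Fourier seasonal covariates cos(2π d/365), sin(2π d/365) of day-of-year.

The resulting :class:`DesignMatrix` records a column→term map so whole term
blocks can be deleted for likelihood-ratio testing.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .data_io import CONTINUOUS_COVARIATES, Dataset

__all__ = [
    "ModelSpec",
    "DesignMatrix",
    "encode_sum_to_zero",
    "legendre_spatial",
    "fourier_seasonal",
    "darcy_flux",
    "build_design",
    "national_comprehensive",
    "national_final",
    "regional_holocene",
]


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the regression.

    ``interactions`` lists (categorical, continuous) pairs whose members
    must also appear as main effects.  ``spatial_poly_degree`` 0 disables
    the coordinate polynomials.
    """

    continuous_terms: tuple[str, ...] = ()
    categorical_terms: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    spatial_poly_degree: int = 0
    seasonal: bool = False
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.spatial_poly_degree not in (0, 1, 2):
            raise ValueError("spatial_poly_degree must be 0, 1 or 2")
        for cat, cont in self.interactions:
            if cat not in self.categorical_terms:
                raise ValueError(f"interaction categorical '{cat}' not a main effect")
            if cont not in self.continuous_terms:
                raise ValueError(f"interaction continuous '{cont}' not a main effect")

    def drop_term(self, term: str) -> "ModelSpec":
        """Remove a covariate and every interaction involving it."""
        return replace(
            self,
            continuous_terms=tuple(t for t in self.continuous_terms if t != term),
            categorical_terms=tuple(t for t in self.categorical_terms if t != term),
            interactions=tuple(
                (a, b) for a, b in self.interactions if term not in (a, b)
            ),
            name=f"{self.name}-minus-{term}",
        )

    def drop_block(self, block: str) -> "ModelSpec":
        """Remove a named term block ('spatial', 'seasonal', an interaction
        'cat:cont', or a covariate with its interactions)."""
        if block == "spatial":
            return replace(self, spatial_poly_degree=0, name=f"{self.name}-minus-spatial")
        if block == "seasonal":
            return replace(self, seasonal=False, name=f"{self.name}-minus-seasonal")
        if ":" in block:
            cat, cont = block.split(":")
            return replace(
                self,
                interactions=tuple(
                    p for p in self.interactions if p != (cat, cont)
                ),
                name=f"{self.name}-minus-{block}",
            )
        return self.drop_term(block)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "name": self.name,
                    "continuous_terms": list(self.continuous_terms),
                    "categorical_terms": list(self.categorical_terms),
                    "interactions": [list(p) for p in self.interactions],
                    "spatial_poly_degree": self.spatial_poly_degree,
                    "seasonal": self.seasonal,
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            continuous_terms=tuple(d.get("continuous_terms", ())),
            categorical_terms=tuple(d.get("categorical_terms", ())),
            interactions=tuple(tuple(p) for p in d.get("interactions", ())),
            spatial_poly_degree=int(d.get("spatial_poly_degree", 0)),
            seasonal=bool(d.get("seasonal", False)),
            name=d.get("name", "custom"),
        )


@dataclass
class DesignMatrix:
    X: np.ndarray                      # n x p, first column is the intercept
    columns: list[str]                 # per-column labels
    term_blocks: dict[str, list[int]]  # term name -> column indices
    bbox: tuple[float, float, float, float] | None  # lon0, lon1, lat0, lat1
    category_levels: dict[str, list[str]] = field(default_factory=dict)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def drop_columns(self, cols: list[int]) -> "DesignMatrix":
        keep = [j for j in range(self.p) if j not in set(cols)]
        remap = {j: i for i, j in enumerate(keep)}
        blocks = {
            t: [remap[j] for j in idx if j in remap]
            for t, idx in self.term_blocks.items()
        }
        blocks = {t: idx for t, idx in blocks.items() if idx}
        return DesignMatrix(
            self.X[:, keep],
            [self.columns[j] for j in keep],
            blocks,
            self.bbox,
            self.category_levels,
        )


def encode_sum_to_zero(levels: list[str], values) -> tuple[np.ndarray, list[str], str]:
    """Sum-to-zero contrast columns for a categorical covariate.

    ``levels`` is the admissible level set; the last level alphabetically is
    the implied one: its rows carry −1 in every column and its coefficient
    equals minus the sum of the reported K−1 coefficients.

    Returns (columns matrix n×(K−1), kept level names, implied level).
    """
    levels = sorted(set(levels))
    observed = sorted(set(values))
    if len(observed) < 2:
        raise ValueError("categorical covariate has a single observed level")
    unknown = set(observed) - set(levels)
    if unknown:
        raise ValueError(f"values outside declared level set: {sorted(unknown)}")
    kept, implied = levels[:-1], levels[-1]
    values = np.asarray(values, dtype=object)
    cols = np.zeros((len(values), len(kept)))
    for j, lev in enumerate(kept):
        cols[values == lev, j] = 1.0
    cols[values == implied, :] = -1.0
    return cols, kept, implied


def implied_level_coefficient(beta_kept) -> float:
    """Coefficient of the implied level under the sum-to-zero constraint."""
    return float(-np.sum(np.asarray(beta_kept, float)))


def _p1(x):
    return x


def _p2(x):
    return 0.5 * (3.0 * x**2 - 1.0)


def legendre_spatial(lon, lat, bbox, degree: int = 2):
    """Legendre polynomial basis of rescaled coordinates.

    Coordinates are affinely mapped to [−1, 1] over ``bbox = (lon0, lon1,
    lat0, lat1)``.  Degree 1 gives P1(x), P1(y); degree 2 adds P2 on each
    axis and the cross products P1·P1, P1·P2, P2·P1 (7 columns total).
    Points outside the bbox are still rescaled, with a warning.
    """
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    lon0, lon1, lat0, lat1 = bbox
    if lon1 <= lon0 or lat1 <= lat0:
        raise ValueError("degenerate bounding box")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    x = 2.0 * (lon - lon0) / (lon1 - lon0) - 1.0
    y = 2.0 * (lat - lat0) / (lat1 - lat0) - 1.0
    if np.any((x < -1 - 1e-9) | (x > 1 + 1e-9) | (y < -1 - 1e-9) | (y > 1 + 1e-9)):
        warnings.warn("coordinates outside design bounding box; rescaling anyway",
                      stacklevel=2)
    cols = [_p1(x), _p1(y)]
    names = ["lon_P1", "lat_P1"]
    if degree == 2:
        cols += [_p2(x), _p2(y), _p1(x) * _p1(y), _p1(x) * _p2(y), _p2(x) * _p1(y)]
        names += ["lon_P2", "lat_P2", "lonP1_latP1", "lonP1_latP2", "lonP2_latP1"]
    return np.column_stack(cols), names


def fourier_seasonal(dates):
    """(cos, sin) of 2π × day-of-year/365.

    Day-of-year uses the 365-day convention; in leap years Feb 29 maps to
    day 60 and later days shift down one so d never exceeds 365.
    """
    def doy(d):
        if isinstance(d, str):
            d = _dt.date.fromisoformat(d)
        if isinstance(d, pd.Timestamp):
            d = d.date()
        day = d.timetuple().tm_yday
        if day == 366:
            day = 365
        return day

    d = np.array([doy(x) for x in np.atleast_1d(np.asarray(dates, dtype=object))],
                 dtype=float)
    ang = 2.0 * np.pi * d / 365.0
    return np.cos(ang), np.sin(ang)


def darcy_flux(k_h, head_gradient):
    """Darcy flux q = −K_h · i (m/d); flow runs down the head gradient."""
    k_h = np.asarray(k_h, float)
    if np.any(k_h < 0):
        raise ValueError("hydraulic conductivity must be nonnegative")
    q = -k_h * np.asarray(head_gradient, float)
    return float(q) if q.ndim == 0 else q


def build_design(
    spec: ModelSpec,
    ds: Dataset,
    bbox: tuple[float, float, float, float] | None = None,
    category_levels: dict[str, list[str]] | None = None,
    validate_rank: bool = True,
) -> DesignMatrix:
    """Assemble the n×p design matrix for a model specification.

    ``bbox`` and ``category_levels`` freeze the coordinate rescaling and
    contrast level sets from a calibration fit so validation data are
    encoded identically; when omitted they are derived from ``ds``.
    """
    df = ds.joined()
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    blocks: dict[str, list[int]] = {"intercept": [0]}
    levels_out: dict[str, list[str]] = {}

    def add(block: str, arr: np.ndarray, labels: list[str]) -> None:
        start = len(names)
        if arr.ndim == 1:
            arr = arr[:, None]
        for k in range(arr.shape[1]):
            cols.append(arr[:, k])
        names.extend(labels)
        blocks.setdefault(block, []).extend(range(start, start + arr.shape[1]))

    for term in spec.continuous_terms:
        if term not in df.columns:
            raise KeyError(f"covariate '{term}' not in dataset")
        v = df[term]
        if v.isna().any():
            bad = df.loc[v.isna(), "site_id"].tolist()
            raise ValueError(f"missing '{term}' for site(s) {bad[:5]}")
        add(term, v.to_numpy(float), [term])

    contrast_cache: dict[str, np.ndarray] = {}
    kept_cache: dict[str, list[str]] = {}
    for term in spec.categorical_terms:
        if term not in df.columns:
            raise KeyError(f"covariate '{term}' not in dataset")
        lv = (category_levels or {}).get(term)
        if lv is None:
            # restrict the declared level set to levels observed in this data
            declared = (ds.geology_codes if term == "geology"
                        else set(df[term].dropna().unique()))
            lv = sorted(set(declared) & set(df[term].dropna().unique()))
        C, kept, implied = encode_sum_to_zero(lv, df[term].tolist())
        contrast_cache[term] = C
        kept_cache[term] = kept
        levels_out[term] = lv
        add(term, C, [f"{term}[{k}]" for k in kept])

    for cat, cont in spec.interactions:
        C = contrast_cache[cat]
        v = df[cont].to_numpy(float)
        add(f"{cat}:{cont}", C * v[:, None],
            [f"{cat}[{k}]:{cont}" for k in kept_cache[cat]])

    if bbox is None:
        bbox = (
            float(df["lon"].min()), float(df["lon"].max()),
            float(df["lat"].min()), float(df["lat"].max()),
        )
    if spec.spatial_poly_degree > 0:
        S, snames = legendre_spatial(df["lon"], df["lat"], bbox,
                                     spec.spatial_poly_degree)
        add("spatial", S, snames)

    if spec.seasonal:
        c, s = fourier_seasonal(df["date"].tolist())
        add("seasonal", np.column_stack([c, s]), ["season_cos", "season_sin"])

    X = np.column_stack(cols)
    if validate_rank:
        zero = np.where(np.all(X == 0, axis=0))[0]
        if zero.size:
            raise ValueError(
                f"all-zero design column(s): {[names[j] for j in zero]}"
            )
    if validate_rank and np.linalg.matrix_rank(X) < X.shape[1]:
        # name one involved column to aid diagnosis
        _, r = np.linalg.qr(X)
        dep = [names[j] for j in np.where(np.abs(np.diag(r)) < 1e-8)[0]]
        raise ValueError(f"rank-deficient design; collinear column(s) near {dep}")
    return DesignMatrix(X, names, blocks, bbox, levels_out)


# ---------------------------------------------------------------------------
# Named presets mirroring the staged national / regional model builds.

_ALL_CONTINUOUS = tuple(["depth"] + CONTINUOUS_COVARIATES)
_INTERACTIONS = (("geology", "depth"), ("geology", "tssc"),
                 ("geology", "pgi_recharge"))


def national_comprehensive() -> ModelSpec:
    """Deliberately overfitted starting model: every candidate covariate,
    geology, its three interactions, degree-2 spatial polynomials and the
    seasonal pair."""
    return ModelSpec(
        continuous_terms=_ALL_CONTINUOUS,
        categorical_terms=("geology",),
        interactions=_INTERACTIONS,
        spatial_poly_degree=2,
        seasonal=True,
        name="national_comprehensive",
    )


def national_final() -> ModelSpec:
    """Reduced model retaining the significant covariates: geology (+3
    interactions), TSSC, hydraulic conductivity, well depth, groundwater
    level trends, mean predevelopment recharge, net recharge change,
    irrigation trends and the coordinate polynomials."""
    return ModelSpec(
        continuous_terms=("depth", "tssc", "k_h", "gwl_trend", "pgi_recharge",
                          "net_recharge_change", "irrigation_trend"),
        categorical_terms=("geology",),
        interactions=_INTERACTIONS,
        spatial_poly_degree=2,
        seasonal=False,
        name="national_final",
    )


def regional_holocene() -> ModelSpec:
    """Final spec refit on Holocene units only (rb/rm/br excluded upstream
    via :func:`cengrm.pipeline.regional_subset`)."""
    return replace(national_final(), name="regional_holocene")
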