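"""Choropleth maps and table export.

Maps join a risk/SIR surface onto user-supplied GeoJSON polygons by
normalized area identifier — never by feature order, which is the classic
silent-misjoin bug in disease mapping. No national geometry is bundled;
any FeatureCollection whose features carry an ``"area"`` property works.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .bym import RiskSurface
from .data import ValidationError, slugify
from .standardize import SirTable

logger = logging.getLogger(__name__)


@dataclass
class ChoroplethSpec:
    value_field: str = "rr_mean"  # sir | rr_mean | exceedance_prob | covariate
    scheme: str = "quantile"  # quantile | equal | manual
    n_classes: int = 5
    breaks: Optional[Sequence[float]] = None  # manual scheme, strictly increasing
    cmap: str = "YlOrRd"
    fmt: str = "png"

    def __post_init__(self) -> None:
        if self.scheme == "manual":
            if self.breaks is None or len(self.breaks) < 1:
                raise ValidationError("manual scheme needs explicit breaks")
            b = list(self.breaks)
            if any(x >= y for x, y in zip(b, b[1:])):
                raise ValidationError("manual breaks must be strictly increasing")
        elif self.n_classes < 2:
            raise ValidationError("need >= 2 classes")


def _surface_frame(surface: Union[RiskSurface, SirTable]) -> pd.DataFrame:
    if isinstance(surface, RiskSurface):
        return surface.table.copy()
    df = surface.table.copy()
    return df


def classify(values: np.ndarray, spec: ChoroplethSpec) -> tuple[np.ndarray, list]:
    """Class index per value plus the class-interval edges."""
    values = np.asarray(values, dtype=float)
    if spec.scheme == "manual":
        edges = np.asarray(spec.breaks, dtype=float)
    elif spec.scheme == "quantile":
        qs = np.linspace(0, 1, spec.n_classes + 1)[1:-1]
        edges = np.unique(np.quantile(values, qs))
    elif spec.scheme == "equal":
        edges = np.linspace(values.min(), values.max(), spec.n_classes + 1)[1:-1]
        edges = np.unique(edges)
    else:
        raise ValidationError(f"unknown classification scheme {spec.scheme!r}")
    if edges.size == 0:
        logger.warning("degenerate values: single-class map")
    classes = np.searchsorted(edges, values, side="right")
    return classes, list(edges)


def render_map(
    surface: Union[RiskSurface, SirTable],
    geometry_path,
    spec: Optional[ChoroplethSpec] = None,
    out_image=None,
    out_geojson=None,
    title: str = "",
):
    """Classified choropleth: writes an image and/or a classified GeoJSON.

    Every area in the surface must have a matching feature (join on
    slugified ``area`` property); unmatched areas are a hard error.
    Returns (classes per area, class edges).
    """
    from shapely.geometry import shape

    spec = spec or ChoroplethSpec()
    df = _surface_frame(surface)
    if spec.value_field not in df.columns:
        raise ValidationError(
            f"value field {spec.value_field!r} not in surface columns "
            f"{list(df.columns)}"
        )
    with open(geometry_path, encoding="utf-8") as fh:
        gj = json.load(fh)
    feats = {slugify(str((f.get("properties") or {}).get("area", ""))): f
             for f in gj.get("features", [])}
    missing = [a for a in df["area"] if slugify(a) not in feats]
    if missing:
        raise ValidationError(f"no geometry for areas: {missing}")

    values = df[spec.value_field].to_numpy(dtype=float)
    classes, edges = classify(values, spec)
    for area, cls, val in zip(df["area"], classes, values):
        props = feats[slugify(area)].setdefault("properties", {})
        props["class"] = int(cls)
        props[spec.value_field] = float(val)

    if out_geojson is not None:
        used = [feats[slugify(a)] for a in df["area"]]
        with open(out_geojson, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": used}, fh)

    if out_image is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.patches import Polygon as MplPolygon
        from matplotlib.collections import PatchCollection

        fig, ax = plt.subplots(figsize=(8, 8))
        cmap = plt.get_cmap(spec.cmap, max(int(classes.max()) + 1, 2))
        patches, colors = [], []
        for area, cls in zip(df["area"], classes):
            geom = shape(feats[slugify(area)]["geometry"])
            polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
            for poly in polys:
                patches.append(MplPolygon(np.asarray(poly.exterior.coords)))
                colors.append(cls)
        coll = PatchCollection(patches, cmap=cmap, edgecolor="black", lw=0.4)
        coll.set_array(np.asarray(colors, dtype=float))
        ax.add_collection(coll)
        ax.autoscale()
        ax.set_aspect("equal")
        ax.set_axis_off()
        labels = _interval_labels(edges, values)
        handles = [
            plt.Rectangle((0, 0), 1, 1, fc=cmap(k)) for k in range(len(labels))
        ]
        ax.legend(handles, labels, title=spec.value_field, loc="lower right",
                  fontsize=8)
        if title:
            ax.set_title(title)
        fig.savefig(out_image, bbox_inches="tight", dpi=150)
        plt.close(fig)
    return classes, edges


def _interval_labels(edges: list, values: np.ndarray) -> list[str]:
    lo = float(np.min(values))
    hi = float(np.max(values))
    bounds = [lo] + [float(e) for e in edges] + [hi]
    return [
        f"{a:.2f} – {b:.2f}" for a, b in zip(bounds[:-1], bounds[1:])
    ]


# ---------------------------------------------------------------------------
# Table export


def export_tables(
    out_dir,
    sir_tables: Sequence[SirTable] = (),
    dic_reports: Sequence = (),
    param_tables: Sequence[pd.DataFrame] = (),
) -> dict[str, Path]:
    """Emit the observed/expected table, the SIR summary table and the
    parameter/DIC table as CSV files; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if sir_tables:
        counts = pd.concat([t.table for t in sir_tables], ignore_index=True)
        p = out_dir / "observed_expected_sir.csv"
        counts.to_csv(p, index=False)
        written["counts"] = p
        rows = []
        for t in sir_tables:
            s = t.summary
            rows.append(
                {
                    "sex": s.sex,
                    "n_cases": s.total_cases,
                    "incidence_rate_per_1e5": (
                        "" if s.incidence_rate is None
                        else round(s.incidence_rate, 2)
                    ),
                    "sir_mean": round(s.mean, 2),
                    "sir_sd": round(s.sd, 2),
                    "sir_max": round(s.max, 2),
                    "sir_min": round(s.min, 2),
                }
            )
        p = out_dir / "sir_summary.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written["sir_summary"] = p
    else:
        for name in ("observed_expected_sir.csv", "sir_summary.csv"):
            p = out_dir / name
            pd.DataFrame().to_csv(p, index=False)

    model_rows = []
    for r in dic_reports:
        model_rows.append(
            {
                "model": r.label,
                "convention": r.convention,
                "dic": r.dic,
                "p_d": r.p_d,
                "minus2loglik": r.minus2loglik,
            }
        )
    p = out_dir / "model_comparison.csv"
    pd.DataFrame(
        model_rows, columns=["model", "convention", "dic", "p_d", "minus2loglik"]
    ).to_csv(p, index=False)
    written["model_comparison"] = p

    if param_tables:
        params = pd.concat(list(param_tables), ignore_index=True)
        p = out_dir / "parameters.csv"
        params.to_csv(p, index=False)
        written["parameters"] = p
    return written
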