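"""Model/Results interface over the NSA measurement pipelines.

``NeckShaftAngleModel`` is built from a region-labeled cloud (from an
array pair, a file, or a DataFrame) and its :meth:`fit` runs the 2D
and/or 3D measurement, returning a ``NeckShaftAngleResults`` object that
carries the angles, axes, diagnostics and a printable summary table.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import RansacConfig
from .io import LabeledPointCloud, read_cloud, write_result
from .measure import NSAResult, measure_nsa_2d, measure_nsa_3d

__all__ = ["NeckShaftAngleModel", "NeckShaftAngleResults"]


class NeckShaftAngleModel:
    """Femoral neck-shaft-angle measurement model for one specimen.

    Parameters
    ----------
    cloud : LabeledPointCloud
        Region-labeled femur points (0 = head, 1 = neck, 2 = shaft), mm.
    ransac : RansacConfig, optional
        Settings for the projected-head circle fit of the 2D method.

    Examples
    --------
    >>> model = NeckShaftAngleModel.from_file("femur.ply")   # doctest: +SKIP
    >>> res = model.fit(method="both")                        # doctest: +SKIP
    >>> print(res.summary())                                  # doctest: +SKIP
    """

    def __init__(self, cloud: LabeledPointCloud, ransac: RansacConfig | None = None):
        self.cloud = cloud
        self.ransac = ransac if ransac is not None else RansacConfig()

    @classmethod
    def from_file(cls, path, format: str | None = None, ransac: RansacConfig | None = None):
        return cls(read_cloud(path, format=format), ransac=ransac)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, id: str = "", ransac: RansacConfig | None = None):
        """Build from a DataFrame with columns x, y, z, label."""
        missing = [c for c in ("x", "y", "z", "label") if c not in df.columns]
        if missing:
            raise ValueError(f"DataFrame is missing column(s) {missing}")
        cloud = LabeledPointCloud(
            points=df[["x", "y", "z"]].to_numpy(dtype=float),
            labels=df["label"].to_numpy(),
            id=id,
        )
        return cls(cloud, ransac=ransac)

    def fit(self, method: str = "both") -> "NeckShaftAngleResults":
        """Run the requested measurement(s); method in {'2d', '3d', 'both'}."""
        if method not in ("2d", "3d", "both"):
            raise ValueError("method must be '2d', '3d' or 'both'")
        results: dict[str, NSAResult] = {}
        if method in ("3d", "both"):
            results["3d"] = measure_nsa_3d(self.cloud)
        if method in ("2d", "both"):
            results["2d"] = measure_nsa_2d(self.cloud, self.ransac)
        return NeckShaftAngleResults(self, results)


class NeckShaftAngleResults:
    """Fitted NSA measurements for one specimen."""

    def __init__(self, model: NeckShaftAngleModel, results: dict[str, NSAResult]):
        self.model = model
        self.results = results

    @property
    def nsa_2d(self) -> float | None:
        r = self.results.get("2d")
        return None if r is None else r.nsa_deg

    @property
    def nsa_3d(self) -> float | None:
        r = self.results.get("3d")
        return None if r is None else r.nsa_deg

    @property
    def difference(self) -> float | None:
        """|NSA_2d - NSA_3d| in degrees, when both methods were run."""
        if self.nsa_2d is None or self.nsa_3d is None:
            return None
        return abs(self.nsa_2d - self.nsa_3d)

    def save(self, directory, stem: str | None = None) -> list[Path]:
        """Write one result JSON per fitted method; returns the paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        stem = stem or (self.model.cloud.id or "specimen")
        paths = []
        for method, res in sorted(self.results.items()):
            paths.append(write_result(res, directory / f"{stem}_nsa_{method}.json"))
        return paths

    def summary(self) -> str:
        """Human-readable summary table of the fitted angles and diagnostics."""
        buf = _stdio.StringIO()
        cid = self.model.cloud.id or "<unnamed>"
        buf.write("Neck-Shaft Angle Measurement\n")
        buf.write("=" * 60 + "\n")
        buf.write(f"specimen: {cid}    points: {len(self.model.cloud)}\n")
        buf.write("-" * 60 + "\n")
        buf.write(f"{'method':<10}{'NSA (deg)':>12}  diagnostics\n")
        for method in ("3d", "2d"):
            res = self.results.get(method)
            if res is None:
                continue
            diag = ", ".join(
                f"{k}={v:.3f}" if isinstance(v, float) else f"{k}={v}"
                for k, v in res.diagnostics.items()
            )
            buf.write(f"{method:<10}{res.nsa_deg:>12.3f}  {diag}\n")
        if self.difference is not None:
            buf.write("-" * 60 + "\n")
            buf.write(f"|2D - 3D| difference: {self.difference:.3f} deg\n")
        buf.write("=" * 60 + "\n")
        return buf.getvalue()

    def __repr__(self) -> str:
        parts = ", ".join(f"nsa_{m}={r.nsa_deg:.2f}" for m, r in sorted(self.results.items()))
        return f"<NeckShaftAngleResults {parts}>"
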