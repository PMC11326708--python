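"""Experiment-file persistence and data/plot export.

An experiment file is a JSON document holding one record per analyzed tube:
the pack name, tube index (top-down), source image name, a reference to the
stored normalized greyscale PNG, the tube's y boundaries, pen-mark columns
and their clock times, conidial band columns, the growth rate (or N/A), and
the raw densitometry trace.  Period estimates are deliberately *not*
persisted: they derive from the stored features and are recomputed on
demand, so editing a mark or peak can never desynchronize a stored period.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import __version__ as _pkg_version
from .calibration import fit_time_calibration
from .densitometry import (
    BandPeakSet,
    DensitometryProfile,
    TimeMarkSet,
    interpolated_band_profile,
    smooth_for_bands,
)
from .errors import RaceTubeError, SchemaError
from .image_io import RaceTubeImage, save_normalized
from .periods import (
    METHODS,
    all_periods,
    cwt_analysis,
    periodogram_lomb_scargle,
    periodogram_sokolove_bushell,
)
from .tube_detection import BoundaryLine

SCHEMA_VERSION = 1


@dataclass
class TubeRecord:
    """Everything persisted for one analyzed race tube."""

    pack_name: str
    tube_index: int
    source_image: str
    greyscale_image_ref: str
    tube_y_bounds: tuple[BoundaryLine, BoundaryLine]
    mark_x: list[float]
    mark_times_h: list[float]
    band_x: list[float]
    growth_rate_mm_per_h: float | None
    raw_densitometry: list[float]

    # -- derived views -------------------------------------------------
    def raw_profile(self) -> DensitometryProfile:
        return DensitometryProfile(
            np.asarray(self.raw_densitometry), "raw", self.tube_index
        )

    def marks(self) -> TimeMarkSet:
        return TimeMarkSet(np.asarray(self.mark_x), np.asarray(self.mark_times_h))

    def band_peaks(self) -> BandPeakSet:
        return BandPeakSet(np.asarray(self.band_x))

    def interpolated_profile(self) -> DensitometryProfile:
        return interpolated_band_profile(self.raw_profile(), self.marks())

    def periods(self, window=None, band_h=(14.0, 40.0)):
        """Recompute the four period estimates from the stored features."""
        return all_periods(
            self.interpolated_profile(), self.marks(), self.band_peaks(),
            window=window, band_h=band_h,
        )

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "pack_name": self.pack_name,
            "tube_index": self.tube_index,
            "source_image": self.source_image,
            "greyscale_image_ref": self.greyscale_image_ref,
            "tube_y_bounds": [
                {"y_left": b.y_left, "y_right": b.y_right, "method": b.method}
                for b in self.tube_y_bounds
            ],
            "mark_x": [float(x) for x in self.mark_x],
            "mark_times_h": [float(t) for t in self.mark_times_h],
            "band_x": [float(x) for x in self.band_x],
            "growth_rate_mm_per_h": self.growth_rate_mm_per_h,
            "raw_densitometry": [float(v) for v in self.raw_densitometry],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TubeRecord":
        bounds = tuple(
            BoundaryLine(b["y_left"], b["y_right"], b["method"])
            for b in d["tube_y_bounds"]
        )
        return cls(
            pack_name=d["pack_name"],
            tube_index=d["tube_index"],
            source_image=d["source_image"],
            greyscale_image_ref=d["greyscale_image_ref"],
            tube_y_bounds=bounds,  # type: ignore[arg-type]
            mark_x=list(d["mark_x"]),
            mark_times_h=list(d["mark_times_h"]),
            band_x=list(d["band_x"]),
            growth_rate_mm_per_h=d["growth_rate_mm_per_h"],
            raw_densitometry=list(d["raw_densitometry"]),
        )


@dataclass
class ExperimentFile:
    """A reloadable collection of tube records plus creation metadata."""

    records: list[TubeRecord] = field(default_factory=list)
    created: str = ""
    schema_version: int = SCHEMA_VERSION


def save_experiment(
    records: list[TubeRecord],
    path: str | Path,
    images: dict[str, RaceTubeImage] | None = None,
    created: str | None = None,
) -> Path:
    """Write an experiment file (JSON) plus one normalized PNG per pack.

    ``images`` maps pack names to their normalized greyscale images; each is
    stored next to the experiment file under the record's
    ``greyscale_image_ref``.  Passing the ``created`` stamp from a loaded
    file makes save -> load -> save byte-identical.
    """
    path = Path(path)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "created": created
        if created is not None
        else datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "generator": f"racetube {_pkg_version}",
        "tubes": [r.to_dict() for r in records],
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
    if images:
        refs = {r.pack_name: r.greyscale_image_ref for r in records}
        for pack, img in images.items():
            ref = refs.get(pack, f"{pack}.png")
            save_normalized(img, path.parent / ref)
    return path


def load_experiment(path: str | Path) -> ExperimentFile:
    """Read an experiment file; unknown schema versions are rejected."""
    path = Path(path)
    doc = json.loads(path.read_text())
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"experiment file schema {version!r} not supported "
            f"(expected {SCHEMA_VERSION})"
        )
    records = [TubeRecord.from_dict(d) for d in doc["tubes"]]
    return ExperimentFile(records=records, created=doc.get("created", ""))


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def _write_csv(path: Path, header: list[str], columns: list[np.ndarray]) -> None:
    import pandas as pd

    pd.DataFrame(dict(zip(header, columns))).to_csv(path, index=False)


def export_all(
    records: list[TubeRecord],
    outdir: str | Path,
    band_h: tuple[float, float] = (14.0, 40.0),
    window=None,
    plots: bool = True,
) -> list[Path]:
    """Export densitometry, spectra, CWT matrices and a periods table.

    Per tube: a densitometry CSV (raw / smoothed / interpolated) and plot,
    Sokolove-Bushell and Lomb-Scargle spectra as CSV (+plots), and the CWT
    amplitude matrix as CSV (+heatmap).  One periods table covers all
    records.  Returns the list of written paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    table_rows = []
    for rec in records:
        stem = f"{rec.pack_name}_tube{rec.tube_index}"
        raw = rec.raw_profile()
        smoothed = smooth_for_bands(raw)
        interp = interpolated_band_profile(raw, rec.marks())
        cal = fit_time_calibration(rec.marks())

        csv = outdir / f"{stem}_densitometry.csv"
        _write_csv(
            csv,
            ["tube_index", "x_px", "raw", "smoothed", "interpolated"],
            [
                np.full(len(raw.values), rec.tube_index),
                raw.x,
                raw.values,
                smoothed.values,
                interp.values,
            ],
        )
        written.append(csv)

        # spectra are optional per tube: a degenerate (e.g. featureless) trace
        # has no periodogram, but its densitometry is still exported
        def _try(fn):
            try:
                return fn()
            except RaceTubeError:
                return None

        sb = _try(lambda: periodogram_sokolove_bushell(interp, cal, band_h))
        ls = _try(lambda: periodogram_lomb_scargle(interp, cal, band_h))
        cw = _try(lambda: cwt_analysis(interp, cal, band_h))
        spectra = [
            (pg, tag)
            for pg, tag in ((sb, "sokolove_bushell"), (ls, "lomb_scargle"))
            if pg is not None
        ]
        for pg, tag in spectra:
            csv = outdir / f"{stem}_{tag}.csv"
            _write_csv(csv, ["period_h", "power"], [pg.periods_h, pg.power])
            written.append(csv)
        if cw is not None:
            csv = outdir / f"{stem}_cwt.csv"
            import pandas as pd

            pd.DataFrame(
                cw.amplitude,
                index=np.round(cw.periods_h, 4),
                columns=np.round(cw.times_h, 4),
            ).to_csv(csv, index_label="period_h")
            written.append(csv)

        if plots:
            fig, ax = plt.subplots(figsize=(9, 3))
            ax.plot(raw.x, raw.values, lw=0.6, label="raw", color="0.6")
            ax.plot(interp.x, interp.values, lw=1.2, label="interpolated")
            for x in rec.mark_x:
                ax.axvline(x, color="r", lw=0.5, alpha=0.6)
            for x in rec.band_x:
                ax.axvline(x, color="b", lw=0.5, alpha=0.4, ls="--")
            ax.set(xlabel="x (px)", ylabel="brightness", title=stem)
            ax.legend(loc="upper right", fontsize=8)
            p = outdir / f"{stem}_densitometry.png"
            fig.savefig(p, dpi=110)
            plt.close(fig)
            written.append(p)

            for pg, tag in spectra:
                fig, ax = plt.subplots(figsize=(5, 3.2))
                ax.plot(pg.periods_h, pg.power)
                ax.axvline(pg.peak_period_h, color="r", lw=0.7, ls="--")
                ax.set(
                    xlabel="period (h)",
                    ylabel="power",
                    title=f"{stem} {tag} (peak {pg.peak_period_h:.2f} h)",
                )
                p = outdir / f"{stem}_{tag}.png"
                fig.savefig(p, dpi=110)
                plt.close(fig)
                written.append(p)

            if cw is not None:
                fig, ax = plt.subplots(figsize=(7, 3.2))
                ax.pcolormesh(cw.times_h, cw.periods_h, cw.amplitude,
                              shading="auto")
                ax.plot(cw.times_h[cw.accepted], cw.ridge_periods_h[cw.accepted],
                        "w.", ms=1.5)
                ax.set(
                    xlabel="time (h)",
                    ylabel="period (h)",
                    title=f"{stem} CWT (mean ridge {cw.period_h:.2f} h)",
                )
                p = outdir / f"{stem}_cwt.png"
                fig.savefig(p, dpi=110)
                plt.close(fig)
                written.append(p)

        estimates = rec.periods(window=window, band_h=band_h)
        for method in METHODS:
            est = estimates[method]
            table_rows.append(
                {
                    "pack": rec.pack_name,
                    "tube": rec.tube_index,
                    "method": method,
                    "period_h": est.period_h,
                    "growth_rate_mm_per_h": (
                        rec.growth_rate_mm_per_h
                        if rec.growth_rate_mm_per_h is not None
                        else "N/A"
                    ),
                }
            )

    import pandas as pd

    table = outdir / "periods.csv"
    pd.DataFrame(table_rows).to_csv(table, index=False)
    written.append(table)
    return written
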