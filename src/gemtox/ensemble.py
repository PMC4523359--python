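"""Posterior ensemble container and serialization.

A fitted model is summarised by a stack of composition draws indexed by
(draw, point, stick).  "Point" is a covariate grid value for the dependent
model and an observed site for the independent one.  The final stick slot
holds the residual (undetected-taxa) tail mass, so every composition sums to
one exactly.  Draws are serialized as a compressed ``.npz`` array container
with a JSON sidecar manifest recording the configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["PosteriorEnsemble"]

_NORM_TOL = 1e-10


@dataclass
class PosteriorEnsemble:
    """Stacked posterior composition draws plus hyperparameter traces.

    Attributes
    ----------
    compositions : (n_draws, n_points, J+1) array; last stick slot is the
        residual tail mass, so each composition sums to 1 within 1e-10.
    grid : covariate value of each point (mg/kg); for an independent per-site
        fit this is the per-site covariate (or the site index when unknown).
    M_trace : per-draw precision values; shape (n_draws,) for the dependent
        model, (n_draws, n_sites) for independent per-site fits.
    bandwidth_trace : per-draw GP bandwidth (rescaled-covariate units), or
        None for the independent model.
    otu_ids : OTU labels in the original table order.
    stick_of_otu : stick column index of each OTU (OTUs are assigned to
        sticks in decreasing order of total abundance).
    """

    compositions: np.ndarray
    grid: np.ndarray
    M_trace: np.ndarray
    bandwidth_trace: np.ndarray | None
    otu_ids: tuple[str, ...]
    stick_of_otu: np.ndarray
    site_ids: tuple[str, ...] | None = None
    genera: tuple[str | None, ...] | None = None
    acceptance_rates: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    # dependent-model extras: fitted compositions at the observed sites
    # (n_draws, n_sites, J+1) and the per-site covariates they belong to
    site_compositions: np.ndarray | None = None
    site_covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        comps = np.asarray(self.compositions, dtype=float)
        if comps.ndim != 3:
            raise ValueError("compositions must be (draws, points, sticks+1)")
        sums = comps.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=_NORM_TOL, rtol=0.0):
            raise ValueError("compositions must sum to 1 within 1e-10")
        if len(self.M_trace) != comps.shape[0]:
            raise ValueError("M_trace length must equal number of draws")
        if self.bandwidth_trace is not None and len(self.bandwidth_trace) != comps.shape[0]:
            raise ValueError("bandwidth_trace length must equal number of draws")
        if len(self.grid) != comps.shape[1]:
            raise ValueError("grid length must equal number of points")
        self.compositions = comps
        self.grid = np.asarray(self.grid, dtype=float)
        self.stick_of_otu = np.asarray(self.stick_of_otu, dtype=np.int64)

    @property
    def n_draws(self) -> int:
        return self.compositions.shape[0]

    @property
    def n_points(self) -> int:
        return self.compositions.shape[1]

    def otu_probabilities(self) -> np.ndarray:
        """Composition draws re-indexed to table OTU order: shape
        (n_draws, n_points, n_otus)."""
        return self.compositions[:, :, self.stick_of_otu]

    def save(self, path: str | Path) -> None:
        """Write a compressed array container plus a JSON manifest sidecar."""
        path = Path(path)
        np.savez_compressed(
            path,
            compositions=self.compositions,
            grid=self.grid,
            M_trace=self.M_trace,
            bandwidth_trace=(np.array([]) if self.bandwidth_trace is None
                             else self.bandwidth_trace),
            stick_of_otu=self.stick_of_otu,
            site_compositions=(np.array([]) if self.site_compositions is None
                               else self.site_compositions),
            site_covariates=(np.array([]) if self.site_covariates is None
                             else self.site_covariates),
        )
        manifest = {
            "otu_ids": list(self.otu_ids),
            "site_ids": None if self.site_ids is None else list(self.site_ids),
            "genera": None if self.genera is None else list(self.genera),
            "acceptance_rates": self.acceptance_rates,
            "meta": self.meta,
            "dims": {"draw": self.n_draws, "point": self.n_points,
                     "stick": self.compositions.shape[2] - 1},
        }
        npz = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
        npz.with_suffix(".json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorEnsemble":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
        manifest = json.loads(path.with_suffix(".json").read_text())
        bw = arrays["bandwidth_trace"]
        return cls(
            compositions=arrays["compositions"],
            grid=arrays["grid"],
            M_trace=arrays["M_trace"],
            bandwidth_trace=None if bw.size == 0 else bw,
            otu_ids=tuple(manifest["otu_ids"]),
            stick_of_otu=arrays["stick_of_otu"],
            site_ids=(None if manifest["site_ids"] is None
                      else tuple(manifest["site_ids"])),
            genera=(None if manifest.get("genera") is None
                    else tuple(manifest["genera"])),
            acceptance_rates=manifest["acceptance_rates"],
            meta=manifest["meta"],
            site_compositions=(None if arrays["site_compositions"].size == 0
                               else arrays["site_compositions"]),
            site_covariates=(None if arrays["site_covariates"].size == 0
                             else arrays["site_covariates"]),
        )
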