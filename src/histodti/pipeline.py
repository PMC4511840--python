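"""End-to-end phantom validation run.

Ties the modules together the way the real analysis ties data together:
render sections from a phantom geometry, run the structure-tensor and
FOD stages on each section, simulate and fit the DWI volume, assign
sections to slices, join the two voxel tables, and compute the report
statistics.  This is the entry point used by the ``compare``/``report``
commands and by the self-validation checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import coreg, dtifit, fodfit, phantom, sttensor, valstats
from .io import PipelineConfig

__all__ = ["PhantomRunResult", "run_phantom_pipeline"]


@dataclass
class PhantomRunResult:
    """Everything a phantom validation run produces."""

    records: pd.DataFrame
    ledger: valstats.ExclusionLedger
    truth: pd.DataFrame
    snr_estimate: float
    summary_by_tissue: pd.DataFrame
    correlations: pd.DataFrame
    fod_table: pd.DataFrame
    dti_table: pd.DataFrame

    def region_records(self, region: str) -> pd.DataFrame:
        """Records of one ground-truth region: 'uni', 'crossing' or 'gm'."""
        merged = self.records.merge(
            self.truth[["i", "j", "k", "axis2", "tensor_axis", "tissue"]].rename(
                columns={"tissue": "true_tissue"}
            ),
            on=["i", "j", "k"],
            how="left",
        )
        is_gm = merged["true_tissue"] == "GM"
        has_axis2 = merged["axis2"].notna()
        if region == "gm":
            return merged[is_gm]
        if region == "crossing":
            return merged[~is_gm & has_axis2]
        if region == "uni":
            return merged[~is_gm & ~has_axis2]
        raise ValueError(f"unknown region {region!r}")


def run_phantom_pipeline(
    geometry: Optional[phantom.PhantomGeometry] = None,
    config: Optional[PipelineConfig] = None,
    *,
    pixel_size_um: float = 2.0,
    voxel_size_um: float = 64.0,
    snr: float = 50.0,
    S0: float = 1000.0,
    section_noise_sd: float = 0.02,
    n_directions: int = 60,
    n_b0: int = 6,
    b_value: float = 3000.0,
    seed: int = 0,
) -> PhantomRunResult:
    """Run the full histology-vs-DTI comparison on a synthetic phantom.

    Defaults are the desk-scale study conditions: 8 sections of
    256 x 256 px at 2 um/px, a 64 um comparison voxel (the 340 um voxel
    of the reference acquisition scaled to the phantom's field of view),
    b = 3000 s/mm^2 with 60 directions plus 6 b=0 volumes, Rician noise
    at SNR 50.
    """
    if geometry is None:
        geometry = phantom.default_phantom_geometry()
    if config is None:
        config = PipelineConfig(fod_voxel_um=voxel_size_um, seed=seed)

    scheme = phantom.make_scheme(
        n_directions=n_directions, n_b0=n_b0, b=b_value, seed=seed
    )

    # histology arm: per-section structure tensors -> voxel FODs
    fods: list[fodfit.VoxelFOD] = []
    for s in range(geometry.n_sections):
        section = phantom.render_section(
            geometry,
            pixel_size_um=pixel_size_um,
            noise_sd=section_noise_sd,
            seed=seed,
            section_id=s,
        )
        _, phi = sttensor.orientation_field(
            section, sigma=config.st_sigma, kernel_size=config.st_kernel
        )
        fods.extend(
            fodfit.build_voxel_fods(
                section,
                phi,
                voxel_size_um=config.fod_voxel_um,
                fwhm_deg=config.fod_fwhm_deg,
                n_components=config.fod_components,
                window_halfwidth_deg=config.fod_window_deg,
                min_valid_fraction=config.fod_min_valid_fraction,
                min_stain=config.fod_min_stain,
            )
        )
    fod_table = fodfit.fods_to_table(fods)

    # section -> slice assignment (1:1 in the phantom: sections are slices)
    pairs = dict(
        coreg.assign_sections(
            section_spacing_um=voxel_size_um,
            slice_thickness_um=voxel_size_um,
            n_sections=geometry.n_sections,
            n_slices=geometry.n_sections,
        )
    )
    fod_table["k"] = fod_table["section_id"].map(pairs)

    # MRI arm: simulate and fit the DWI volume
    dwi, tissue, truth = phantom.simulate_dwi(
        geometry,
        scheme,
        voxel_size_um=voxel_size_um,
        S0=S0,
        snr=snr,
        seed=seed,
    )
    dti_table = dtifit.fit_volume(dwi, scheme, tissue)

    # SNR check in a signal-free background corner of the b=0 volumes
    b0 = dwi[..., scheme.bvals == 0]
    corner = (slice(0, max(2, dwi.shape[0] // 4)),
              slice(0, max(2, dwi.shape[1] // 4)),
              slice(None))
    if np.isfinite(snr):
        snr_estimate = dtifit.estimate_snr(b0, tissue > 0, corner)
    else:
        snr_estimate = float("inf")

    records, ledger = valstats.build_voxel_table(
        fod_table,
        dti_table,
        min_valid_fraction=config.fod_min_valid_fraction,
        min_stain=config.fod_min_stain,
        max_out_of_plane_deg=config.dti_max_oop_deg,
    )

    summary = valstats.summarize_differences(
        records, by=("tissue",), min_bin_n=config.stats_min_bin_n
    )
    corr_vars = ["diff", "fa", "md", "rd", "stain", "ampl1", "width1", "ampl2"]
    correlations, _ = valstats.sectionwise_correlations(records, corr_vars)

    return PhantomRunResult(
        records=records,
        ledger=ledger,
        truth=truth,
        snr_estimate=snr_estimate,
        summary_by_tissue=summary,
        correlations=correlations,
        fod_table=fod_table,
        dti_table=dti_table,
    )
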