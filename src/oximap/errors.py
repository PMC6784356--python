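"""Exception hierarchy shared across the pipeline stages."""


class OximapError(Exception):
    """Base class for all package-specific errors."""


class ShapeError(OximapError):
    """Array geometry incompatible with the mosaic/cube contract."""


class CalibrationReferenceError(OximapError):
    """White/dark reference frames unusable (white <= dark too often)."""


class UnmixingError(OximapError):
    """Channel-mixing matrix singular or too ill-conditioned to invert."""


class BandSelectionError(OximapError):
    """Ambiguous or out-of-range spectral band request."""


class ChromophoreRangeError(OximapError):
    """Wavelength outside the tabulated chromophore support (no extrapolation)."""


class DegenerateAbsorptionError(OximapError):
    """mu_a = 0 makes the diffusion penetration depth undefined."""


class ModelEvaluationError(OximapError):
    """Two-layer forward model produced a non-finite or singular result."""


class SegmentationError(OximapError):
    """Clustering preconditions violated (ROI too small, non-finite spectra)."""


class FitError(OximapError):
    """All inversion starts failed to produce a finite loss."""


class PhantomError(OximapError):
    """Invalid synthetic-phantom specification (degenerate layout etc.)."""


class PipelineStageError(OximapError):
    """Wraps an error with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
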