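"""Exception hierarchy shared across the segmentation pipeline."""


class DermsegError(Exception):
    """Base class for all package-specific errors."""


class DegenerateImageError(DermsegError, ValueError):
    """Raised when an image has a single occupied gray level, so no
    threshold can separate foreground from background."""


class EmptySeedError(DermsegError, ValueError):
    """Raised when a contour is requested from an empty seed mask."""


class SeedSelectionError(DermsegError, RuntimeError):
    """Raised when the automatic seed-mask stage produces an empty mask.

    Carries diagnostics useful for debugging: the selected threshold (if
    one was found) and the component sizes observed before cleanup.
    """

    def __init__(self, message, threshold=None, component_sizes=None):
        super().__init__(message)
        self.threshold = threshold
        self.component_sizes = component_sizes or []
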