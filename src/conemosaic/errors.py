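"""Package-specific error types."""


class DegenerateFieldError(ValueError):
    """Raised when a requested lattice cannot fit in the window, or a point
    configuration is too degenerate for a tessellation."""


class PackingError(RuntimeError):
    """Raised when soma-constrained random placement cannot satisfy the
    requested density. Carries the class that failed to place."""

    def __init__(self, cone_class: str, placed: int, requested: int, attempts: int,
                 message: str | None = None):
        self.cone_class = cone_class
        self.placed = placed
        self.requested = requested
        if message is None:
            message = (
                f"could not place {cone_class!r} cone {placed + 1}/{requested} "
                f"after {attempts} consecutive rejections; requested packing is "
                "too dense"
            )
        super().__init__(message)
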