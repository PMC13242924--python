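"""Exception hierarchy.

Every error raised while decoding, encoding or validating carries the
slash-separated path of the offending element inside the HDF5 container,
so failures in deeply nested slots (``/uns/a/b/c``) are addressable.
"""

from __future__ import annotations


class H5adKitError(Exception):
    """Base class for all package errors."""


class EncodingError(H5adKitError):
    """An element could not be decoded or encoded.

    Parameters
    ----------
    path:
        Slash-separated location of the element inside the container.
    message:
        Human-readable description of the problem.
    """

    def __init__(self, path: str, message: str):
        self.path = path or "/"
        super().__init__(f"{self.path}: {message}")


class ElementValidationError(EncodingError):
    """A decoded element violates a structural invariant (e.g. a sparse
    index out of range, or a categorical code pointing past the category
    list)."""


class ContainerValidationError(H5adKitError):
    """A container-level shape invariant is violated.

    Names the first violated slot together with the expected and actual
    dimensions.
    """

    def __init__(self, slot: str, message: str):
        self.slot = slot
        super().__init__(f"slot '{slot}': {message}")


class ConversionError(H5adKitError):
    """A conversion between container layouts cannot proceed."""
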