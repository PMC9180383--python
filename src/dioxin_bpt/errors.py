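"""Exception types shared across the pipeline stages."""

from __future__ import annotations


class DioxinBPTError(Exception):
    """Base class for all package errors."""


class ValidationError(DioxinBPTError, ValueError):
    """A table or parameter violates an invariant.

    ``key`` carries the offending index key (e.g. an ``(age_group, region)``
    tuple) so callers can localise the defect without parsing the message.
    """

    def __init__(self, message: str, *, key: object = None):
        super().__init__(message)
        self.key = key


class StageError(DioxinBPTError, RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original
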