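"""Shared exception types and the package logger."""

import logging

logger = logging.getLogger("zfbattery")


class ValidationError(ValueError):
    """An input violates a documented contract (bad config, malformed file,
    degenerate data where the operation is undefined)."""
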