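"""Exception hierarchy shared across the package."""


class SomnopostureError(Exception):
    """Base class for all package errors."""


class ConfigError(SomnopostureError):
    """Invalid configuration, scenario, or truth-table override."""


class DataError(SomnopostureError):
    """Malformed or inconsistent input data (streams, profiles)."""


class SlotExhaustedError(SomnopostureError):
    """All eight adaptive posture slots of a subject profile are occupied."""
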