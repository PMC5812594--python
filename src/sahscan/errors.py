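"""Exception hierarchy."""


class SahScanError(Exception):
    """Base class for all sahscan errors."""


class ConfigError(SahScanError):
    """Invalid configuration, scoring matrix, or window setup."""


class InputError(SahScanError):
    """Invalid input data (sequences, identifiers, files)."""


class AnalysisError(SahScanError):
    """Analysis requested on data that cannot support it."""
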