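"""Exception hierarchy."""


class FertTxError(Exception):
    """Base class for pipeline errors."""


class ConfigError(FertTxError):
    """Invalid or inconsistent configuration."""


class PlacementError(ConfigError):
    """Synthetic genes cannot be placed on the requested chromosome."""


class UntestableLocusError(FertTxError):
    """A locus cannot be tested under the requested null model."""
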