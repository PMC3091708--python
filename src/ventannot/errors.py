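"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: InputError / FormatError -> 1,
ConfigError -> 2.
"""


class VentannotError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(VentannotError):
    """Invalid configuration or parameters."""


class InputError(VentannotError):
    """Malformed or inconsistent input records."""


class FormatError(VentannotError):
    """A file violates its declared format (cycles, dangling references...)."""


class TrainingError(VentannotError):
    """Codon-model training impossible (no training codons)."""


class TaxonomyLookupError(VentannotError):
    """A taxid is absent from the taxonomy table."""
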