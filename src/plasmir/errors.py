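"""Exception hierarchy shared across the package."""


class PlasmirError(Exception):
    """Base class for all package errors."""


class GenerationError(PlasmirError):
    """Synthetic-data generation failed (e.g. name collision, empty library)."""


class ConfigurationError(PlasmirError):
    """An input configuration is inconsistent (panels, parameters, paths)."""


class InputError(PlasmirError):
    """A data input violates a precondition (bad alphabet, missing assay...)."""


class ParseError(PlasmirError):
    """A file could not be parsed; carries the offending record index."""
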