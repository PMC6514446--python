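"""Exception hierarchy shared across the package."""


class HaplodoseError(Exception):
    """Base class for all package errors."""


class InputError(HaplodoseError):
    """Malformed or inconsistent user input (files, labels, counts)."""


class AlignmentError(InputError):
    """Sequences that should form an alignment do not (ragged lengths, etc.)."""


class AnnotationError(InputError):
    """Gene annotation inconsistent with the sequence it annotates."""


class ConfigError(HaplodoseError):
    """Invalid configuration value (thresholds, rates, ploidies)."""


class SaturationError(HaplodoseError):
    """A distance correction was requested outside its log domain."""
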