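"""Exception types shared across the pipeline."""


class RsipipeError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(RsipipeError):
    """A config object violates its invariants (bad probabilities, b-values...)."""


class CohortIOError(RsipipeError):
    """Cohort files missing or unreadable on disk."""


class LeakageError(RsipipeError):
    """A model was (about to be) fit on patients from its own held-out site."""
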