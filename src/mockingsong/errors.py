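"""Exception types shared across the pipeline."""


class InputError(ValueError):
    """Raised when an input file, track, or parameter violates a precondition."""


class InsufficientDistantPhrases(Exception):
    """Signal that a focal phrase has fewer eligible distant phrases than requested.

    Callers iterating over a song catch this and drop the focal phrase from
    the analysis rather than aborting the whole run.
    """
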