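"""Shared exception types."""


class ValidationError(ValueError):
    """Raised when input data violate a schema or domain invariant.

    The CLI maps this exception to exit code 2 so that scripted pipelines
    can distinguish bad input from internal failures.
    """
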