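"""Exception hierarchy shared across the pipeline."""


class CiberError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(CiberError):
    """Invalid user input: malformed files, bad configuration, missing samples.

    ``problems`` carries one message per violation so callers can report
    everything at once instead of failing on the first field.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))
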