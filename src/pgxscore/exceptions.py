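"""Package exception hierarchy."""

from __future__ import annotations


class PgxScoreError(Exception):
    """Base class for all pgxscore errors."""


class ConfigurationError(PgxScoreError):
    """Invalid simulation or pipeline configuration."""


class ParseError(PgxScoreError):
    """Malformed input file.

    Parameters
    ----------
    path : str
        File in which the problem was found.
    line : int or None
        1-based line number when known.
    message : str
        Description of the problem.
    """

    def __init__(self, path, line, message):
        self.path = str(path)
        self.line = line
        loc = f"{self.path}:{line}" if line is not None else self.path
        super().__init__(f"{loc}: {message}")


class EmptyPanelError(PgxScoreError):
    """Every SNP was removed by quality control."""


class PipelineError(PgxScoreError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, message):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
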