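"""Exception hierarchy for the screen pipeline."""


class G1ScreenError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(G1ScreenError):
    """Invalid simulation or run configuration."""


class NoSeparationError(G1ScreenError):
    """Control intensity distributions do not separate enough to place a gate."""


class DegenerateControlsError(G1ScreenError):
    """Positive and negative control means coincide; Z' is undefined."""


class MissingChannelError(G1ScreenError):
    """A required intensity channel is absent from the cell records."""


class MissingColumnError(G1ScreenError):
    """A required column is absent from an input table."""


class TableFormatError(G1ScreenError):
    """An input table is malformed (duplicates, non-numeric fields, empty)."""


class StageError(G1ScreenError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
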