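"""Exception hierarchy shared across the pipeline stages."""


class PthSpeechError(Exception):
    """Base class for all package-specific errors."""


class AudioFormatError(PthSpeechError):
    """Input file is not readable PCM WAV."""


class EmptySignalError(PthSpeechError):
    """Audio contains no samples."""


class NoSpeechError(PthSpeechError):
    """Voice activity detection found no speech to measure."""


class EmptyPromptError(PthSpeechError):
    """Sentence prompt text is empty."""


class InsufficientVoicingError(PthSpeechError):
    """Fewer than two voiced frames; pitch statistics undefined."""


class DegenerateAreaError(PthSpeechError):
    """Too few distinct formant points to span an area."""


class AlignmentError(PthSpeechError):
    """Forced alignment infeasible (fewer frames than phones)."""


class UnknownPhoneError(PthSpeechError):
    """Phone label missing from the acoustic model inventory."""


class MissingClassError(PthSpeechError):
    """No phone segments of the requested class (vowel/consonant)."""


class UnmatchableReferenceError(PthSpeechError):
    """Normative corpus contains no records of the requested sex."""


class ValidationError(PthSpeechError):
    """Questionnaire response violates the instrument's item structure."""


class FittingInconsistencyError(PthSpeechError):
    """Nested model fits are inconsistent (reduced beats full)."""
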