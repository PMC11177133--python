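"""Exception hierarchy shared across the package."""


class SvldError(Exception):
    """Base class for all svld errors."""


class AlignmentError(SvldError):
    """Two per-sample vectors are not aligned (length/order mismatch)."""


class NoDataError(SvldError):
    """No usable observations remain (e.g. all samples missing)."""


class DegenerateError(SvldError):
    """A locus is monomorphic, so an LD quantity is undefined."""


class MalformedRecordError(SvldError):
    """A variant record lacks required coordinate/span metadata."""


class NoCommonSamplesError(SvldError):
    """Two genotype panels share no sample IDs."""


class FormatError(SvldError):
    """An input file does not conform to the expected dialect."""


class FeasibilityError(SvldError):
    """Requested haplotype parameters are outside the admissible region."""


class FixtureError(SvldError):
    """Synthetic fixture specification is internally inconsistent."""


class InternalConsistencyError(SvldError):
    """A numerical invariant was violated beyond floating tolerance."""
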