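"""Exception types raised across the package."""


class MihtError(Exception):
    """Base class for all package-specific errors."""


class PlinkFormatError(MihtError):
    """A .bed file lacks the PLINK magic bytes or uses an unsupported mode."""


class PlinkConsistencyError(MihtError):
    """.bed payload size disagrees with the .bim/.fam row counts."""


class MonomorphicVariantError(MihtError):
    """A variant with zero genotype variance cannot be standardized."""


class DefinitenessError(MihtError):
    """A matrix required to be symmetric positive definite is not."""


class SingularResidualError(MihtError):
    """The residual covariance is rank deficient; the precision update is undefined."""
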