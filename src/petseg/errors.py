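"""Exception types shared across the package."""


class PetsegError(Exception):
    """Base class for petseg errors."""


class PlacementInfeasibleError(PetsegError):
    """Raised when a phantom tumor cannot be placed inside the body at the
    requested bladder gap."""


class AlignmentError(PetsegError):
    """Raised when an image and a mask disagree in shape or voxel spacing."""


class DegenerateInputError(PetsegError):
    """Raised when an input has no usable signal (e.g. all-zero scan, or a
    constant body that leaves the Z-score undefined)."""


class ConfigError(PetsegError):
    """Raised for inconsistent model / training configuration."""


class ShapeError(PetsegError):
    """Raised when tensor spatial dimensions violate an architectural
    constraint (e.g. not divisible by the downsampling factor)."""


class CheckpointError(PetsegError):
    """Raised when a checkpoint does not match the model configuration."""
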