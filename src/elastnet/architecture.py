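"""CNN architecture and training hyperparameter definitions.

Both regressors share the same stage layout: four 1-D convolutions
(kernel 5, stride 2, padding 2), each followed by ReLU, then a single
max-pool (kernel 3, stride 2), a flatten, and an affine head that emits
the scalar elastance. They differ only in channel progression:

    one-channel  (CNN_1):  1 -> 2 -> 4 -> 8 -> 16,  flatten 16*6 = 96
    two-channel  (CNN_2):  2 -> 8 -> 16 -> 18 -> 24, flatten 24*6 = 144

With a 200-sample input the spatial chain is 200 -> 100 -> 50 -> 25 ->
13 -> (pool) 6.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["layer_output_length", "CNNArchitecture", "TrainingConfig"]


def layer_output_length(L_in: int, kernel: int, stride: int, padding: int) -> int:
    """Output length of a 1-D convolution/pooling stage.

    floor((L_in + 2*padding - kernel)/stride) + 1; raises if the input is
    too short to produce any output.
    """
    if L_in + 2 * padding < kernel:
        raise ValueError(f"input of length {L_in} too short for kernel {kernel}")
    out = (L_in + 2 * padding - kernel) // stride + 1
    if out <= 0:
        raise ValueError("convolution produces no output")
    return out


@dataclass(frozen=True)
class CNNArchitecture:
    """Channel progression and stage geometry of one regressor."""

    in_channels: int
    conv_out_channels: tuple[int, int, int, int]
    kernel: int = 5
    stride: int = 2
    padding: int = 2
    pool_kernel: int = 3
    pool_stride: int = 2
    input_length: int = 200

    def __post_init__(self) -> None:
        if self.in_channels not in (1, 2):
            raise ValueError("in_channels must be 1 or 2")
        if len(self.conv_out_channels) != 4:
            raise ValueError("exactly four convolution stages are required")

    @classmethod
    def cnn1(cls) -> "CNNArchitecture":
        """One-channel regressor: pressure wave only."""
        return cls(in_channels=1, conv_out_channels=(2, 4, 8, 16))

    @classmethod
    def cnn2(cls) -> "CNNArchitecture":
        """Two-channel regressor: pressure wave + time derivative."""
        return cls(in_channels=2, conv_out_channels=(8, 16, 18, 24))

    @property
    def conv_lengths(self) -> tuple[int, ...]:
        """Spatial length after each convolution stage."""
        lens = []
        L = self.input_length
        for _ in self.conv_out_channels:
            L = layer_output_length(L, self.kernel, self.stride, self.padding)
            lens.append(L)
        return tuple(lens)

    @property
    def pooled_length(self) -> int:
        return layer_output_length(self.conv_lengths[-1], self.pool_kernel, self.pool_stride, 0)

    @property
    def flatten_width(self) -> int:
        """Width of the feature vector entering the affine head."""
        w = self.conv_out_channels[-1] * self.pooled_length
        if w <= 0:
            raise ValueError("flatten width must be positive")
        return w

    @property
    def kernel_slice_totals(self) -> tuple[int, ...]:
        """Per-layer filters x input-channels (architecture audit)."""
        chans = (self.in_channels,) + tuple(self.conv_out_channels)
        return tuple(chans[i] * chans[i + 1] for i in range(4))


@dataclass(frozen=True)
class TrainingConfig:
    """Training recipe: Adam at lr 1e-3 on MSE, batch size and epoch count
    tuned on the validation partition."""

    learning_rate: float = 0.001
    batch_size_grid: tuple[int, ...] = (32, 64, 128)
    max_epochs: int = 400
    seed: int = 0
    loss: str = "mse"

    def __post_init__(self) -> None:
        if not self.batch_size_grid:
            raise ValueError("batch size grid must be nonempty")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.loss != "mse":
            raise ValueError("only the MSE loss is supported")
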