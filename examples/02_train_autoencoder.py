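"""Train the LSTM seq2seq autoencoder on half-streamline prediction.

The encoder reads the first half of each streamline (plus a (0,0,0) end
token); the decoder, started from the encoder's states and a (0,0,0) start
token, predicts the second half point by point, feeding back its own
outputs (no teacher forcing). Validation MSE is in mm^2 per coordinate.
"""

from tractembed import (ModelConfig, SeqAEModel, TrainConfig,
                        count_parameters, generate_synthetic_atlas, train)

config = ModelConfig(hidden_dim=64, n_layers=1)
print(f"model: hidden={config.hidden_dim}, layers={config.n_layers}, "
      f"{count_parameters(config):,} trainable parameters")
print(f"(the reference 128-hidden model has "
      f"{count_parameters(ModelConfig(hidden_dim=128)):,})")

tracts = generate_synthetic_atlas(seed=1, n_per_bundle=60)
model = SeqAEModel.initialize(config, seed=1)
best, log = train(model, tracts, TrainConfig(max_epochs=8, seed=1))

print(f"\ntrained on {len(tracts)} streamlines, initial val MSE "
      f"{log.initial_val_loss:.1f} mm^2")
for row in log.as_rows():
    print(f"  epoch {row['epoch']}: train {row['train_loss']:8.1f}   "
          f"val {row['val_loss']:8.1f}")
print(f"kept epoch {log.best_epoch} (lowest validation loss). With this few "
      "streamlines per epoch the loss falls slowly; longer corpora or more "
      "epochs drive it near zero.")

best.save("scratch/example_model.ckpt")
print("checkpoint -> scratch/example_model.ckpt")
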