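model_id,beta1,beta2,epsilon,aic
1,10501.2,-28.8,0.173,2726.3
2,12160.7,,-0.216,2770.5
3,,-30.0,0.878,2737.2
4,,,0.573,2785.1
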