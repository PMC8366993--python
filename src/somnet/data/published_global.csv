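variant,local_avg,external_avg,ensemble_avg,i_vs_ii,i_vs_iii,ii_vs_iii
CNN_1,0.7417,0.5333,0.6167,-0.2083,-0.125,0.0833
CNN_3,0.7367,0.5117,0.6133,-0.225,-0.1233,0.1017
CNN_5,0.7217,0.4783,0.5833,-0.2433,-0.1383,0.105
CNN_7,0.7133,0.485,0.59,-0.2283,-0.1233,0.105
CNN_LSTM_3,0.7967,0.5433,0.625,-0.2533,-0.1717,0.0817
CNN_LSTM_5,0.8017,0.5433,0.6267,-0.2583,-0.175,0.0833
CNN_LSTM_7,0.7733,0.535,0.6133,-0.2383,-0.16,0.0783
CNN_F_1,0.74,0.4683,0.545,-0.2717,-0.195,0.0767
CNN_F_3,0.73,0.4433,0.535,-0.2867,-0.195,0.0917
CNN_F_5,0.7167,0.4183,0.5117,-0.2983,-0.205,0.0933
CNN_F_7,0.7117,0.415,0.5083,-0.2967,-0.2033,0.0933
CNN_LSTM_F_3,0.8,0.4617,0.5417,-0.3383,-0.2583,0.08
CNN_LSTM_F_5,0.7983,0.4683,0.5517,-0.33,-0.2467,0.0833
CNN_LSTM_F_7,0.7783,0.4417,0.5333,-0.3367,-0.245,0.0917
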