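dataset,variant,local,ext_min,ext_max,ext_avg,ensemble
HMC,CNN_1,0.74,0.51,0.60,0.54,0.61
HMC,CNN_3,0.71,0.42,0.60,0.5,0.58
HMC,CNN_5,0.7,0.37,0.57,0.46,0.55
HMC,CNN_7,0.69,0.34,0.55,0.44,0.53
HMC,CNN_LSTM_3,0.78,0.50,0.61,0.55,0.62
HMC,CNN_LSTM_5,0.79,0.49,0.62,0.55,0.63
HMC,CNN_LSTM_7,0.77,0.51,0.61,0.55,0.62
HMC,CNN_F_1,0.74,0.39,0.62,0.53,0.61
HMC,CNN_F_3,0.71,0.37,0.63,0.51,0.6
HMC,CNN_F_5,0.7,0.35,0.61,0.48,0.58
HMC,CNN_F_7,0.69,0.35,0.58,0.47,0.56
HMC,CNN_LSTM_F_3,0.77,0.38,0.64,0.53,0.62
HMC,CNN_LSTM_F_5,0.75,0.37,0.65,0.54,0.64
HMC,CNN_LSTM_F_7,0.74,0.34,0.62,0.52,0.63
Dublin,CNN_1,0.68,0.41,0.53,0.49,0.6
Dublin,CNN_3,0.66,0.34,0.57,0.49,0.62
Dublin,CNN_5,0.64,0.32,0.59,0.49,0.6
Dublin,CNN_7,0.67,0.31,0.57,0.46,0.59
Dublin,CNN_LSTM_3,0.77,0.38,0.58,0.51,0.63
Dublin,CNN_LSTM_5,0.79,0.39,0.58,0.51,0.63
Dublin,CNN_LSTM_7,0.77,0.42,0.57,0.51,0.62
Dublin,CNN_F_1,0.65,0.01,0.20,0.09,0.08
Dublin,CNN_F_3,0.64,0.01,0.15,0.07,0.04
Dublin,CNN_F_5,0.61,0.01,0.04,0.03,0.01
Dublin,CNN_F_7,0.66,0.01,0.14,0.07,0.03
Dublin,CNN_LSTM_F_3,0.77,0.01,0.24,0.08,0.06
Dublin,CNN_LSTM_F_5,0.79,0.01,0.22,0.07,0.05
Dublin,CNN_LSTM_F_7,0.78,0.01,0.17,0.06,0.04
SHHS,CNN_1,0.75,0.42,0.64,0.54,0.62
SHHS,CNN_3,0.79,0.30,0.63,0.53,0.65
SHHS,CNN_5,0.79,0.27,0.63,0.49,0.61
SHHS,CNN_7,0.76,0.26,0.65,0.5,0.65
SHHS,CNN_LSTM_3,0.84,0.42,0.62,0.54,0.62
SHHS,CNN_LSTM_5,0.82,0.46,0.67,0.54,0.61
SHHS,CNN_LSTM_7,0.77,0.46,0.66,0.54,0.61
SHHS,CNN_F_1,0.76,0.35,0.68,0.54,0.66
SHHS,CNN_F_3,0.79,0.29,0.65,0.49,0.62
SHHS,CNN_F_5,0.78,0.32,0.68,0.5,0.62
SHHS,CNN_F_7,0.77,0.28,0.67,0.48,0.62
SHHS,CNN_LSTM_F_3,0.83,0.29,0.68,0.52,0.62
SHHS,CNN_LSTM_F_5,0.82,0.31,0.66,0.51,0.62
SHHS,CNN_LSTM_F_7,0.79,0.22,0.67,0.5,0.62
Telemetry,CNN_1,0.76,0.48,0.67,0.56,0.67
Telemetry,CNN_3,0.75,0.42,0.60,0.51,0.61
Telemetry,CNN_5,0.72,0.43,0.60,0.53,0.62
Telemetry,CNN_7,0.7,0.38,0.52,0.46,0.58
Telemetry,CNN_LSTM_3,0.81,0.45,0.68,0.57,0.67
Telemetry,CNN_LSTM_5,0.8,0.43,0.69,0.57,0.69
Telemetry,CNN_LSTM_7,0.8,0.48,0.67,0.58,0.68
Telemetry,CNN_F_1,0.77,0.39,0.70,0.55,0.66
Telemetry,CNN_F_3,0.71,0.46,0.67,0.56,0.66
Telemetry,CNN_F_5,0.73,0.41,0.63,0.49,0.62
Telemetry,CNN_F_7,0.71,0.33,0.64,0.48,0.63
Telemetry,CNN_LSTM_F_3,0.81,0.43,0.72,0.56,0.69
Telemetry,CNN_LSTM_F_5,0.83,0.44,0.71,0.58,0.7
Telemetry,CNN_LSTM_F_7,0.82,0.44,0.68,0.56,0.68
DREAMS,CNN_1,0.76,0.34,0.71,0.54,0.61
DREAMS,CNN_3,0.76,0.34,0.71,0.52,0.61
DREAMS,CNN_5,0.75,0.31,0.68,0.42,0.56
DREAMS,CNN_7,0.73,0.27,0.67,0.53,0.63
DREAMS,CNN_LSTM_3,0.83,0.43,0.73,0.55,0.61
DREAMS,CNN_LSTM_5,0.83,0.41,0.75,0.55,0.59
DREAMS,CNN_LSTM_7,0.78,0.42,0.74,0.52,0.58
DREAMS,CNN_F_1,0.77,0.39,0.70,0.54,0.62
DREAMS,CNN_F_3,0.78,0.25,0.67,0.51,0.66
DREAMS,CNN_F_5,0.75,0.36,0.65,0.5,0.64
DREAMS,CNN_F_7,0.72,0.32,0.71,0.5,0.63
DREAMS,CNN_LSTM_F_3,0.83,0.32,0.71,0.52,0.61
DREAMS,CNN_LSTM_F_5,0.84,0.31,0.72,0.54,0.64
DREAMS,CNN_LSTM_F_7,0.8,0.16,0.71,0.48,0.59
ISRUC,CNN_1,0.76,0.29,0.63,0.53,0.59
ISRUC,CNN_3,0.75,0.29,0.64,0.52,0.61
ISRUC,CNN_5,0.73,0.26,0.63,0.48,0.58
ISRUC,CNN_7,0.73,0.24,0.57,0.47,0.56
ISRUC,CNN_LSTM_3,0.8,0.36,0.65,0.54,0.6
ISRUC,CNN_LSTM_5,0.78,0.42,0.66,0.54,0.61
ISRUC,CNN_LSTM_7,0.75,0.38,0.60,0.51,0.57
ISRUC,CNN_F_1,0.75,0.42,0.68,0.56,0.64
ISRUC,CNN_F_3,0.75,0.35,0.65,0.52,0.63
ISRUC,CNN_F_5,0.73,0.37,0.66,0.51,0.6
ISRUC,CNN_F_7,0.72,0.35,0.62,0.49,0.58
ISRUC,CNN_LSTM_F_3,0.79,0.40,0.68,0.56,0.65
ISRUC,CNN_LSTM_F_5,0.76,0.43,0.69,0.57,0.66
ISRUC,CNN_LSTM_F_7,0.74,0.29,0.66,0.53,0.64
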